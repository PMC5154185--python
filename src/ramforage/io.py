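"""CSV readers/writers with schema validation and provenance headers.

All tables are comma-separated UTF-8 with a header row and ``""`` for missing
values. Every file this package writes starts with a ``# provenance:`` comment
line carrying the seed, config hash and package version, and readers skip
``#`` comment lines, so write-then-read round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import MalformedRecordError, SchemaError
from .maze import FlowerArray, VisitSequence, build_flower_array, validate_sequence
from .simulate import TransitionMatrix

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_matrix_csv",
    "write_matrix_csv",
    "sequences_from_tables",
    "provenance_line",
]

logger = logging.getLogger(__name__)

#: required columns and dtypes per table kind
SCHEMAS = {
    "bees": {
        "bee_id": str,
        "colony_id": str,
        "thorax_width_mm": float,
        "treatment": str,
        "dose_ng": float,
    },
    "visits": {
        "bee_id": str,
        "colony_id": str,
        "bout_index": int,
        "phase": str,
        "visit_index": int,
        "flower_id": int,
    },
    "bouts": {"bee_id": str, "bout_index": int, "phase": str, "duration_s": float},
}


def provenance_line(seed, config_hash: str, version: str) -> str:
    return f"# provenance: seed={seed} config_hash={config_hash} version={version}"


def write_table(
    df: pd.DataFrame, path, provenance: Optional[dict] = None
) -> Path:
    """Write a CSV with an optional leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(
                provenance_line(
                    provenance.get("seed"),
                    provenance.get("config_hash", ""),
                    provenance.get("version", ""),
                )
                + "\n"
            )
        df.to_csv(fh, index=False)
    return path


def read_table(path, kind: Optional[str] = None) -> pd.DataFrame:
    """Read a CSV, validating columns and types against the declared schema.

    Unknown extra columns are preserved with a warning; a missing required
    column or an uncoercible value raises :class:`SchemaError` naming the
    column (and row, for value errors).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False, na_values=[""])
    if kind is None:
        return df
    schema = SCHEMAS[kind]
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    extra = set(df.columns) - set(schema)
    if extra:
        logger.warning("%s: extra column(s) %s preserved", path, sorted(extra))
    for col, typ in schema.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(f"{path}: column {col!r} row {row}: not numeric ({df[col][bad.idxmax()]!r})")
        if typ is int:
            nonint = converted.notna() & (converted != converted.round())
            if nonint.any():
                row = int(nonint.idxmax()) + 2
                raise SchemaError(f"{path}: column {col!r} row {row}: not an integer")
            df[col] = pd.array(converted.round(), dtype="Int64")
        else:
            df[col] = converted
    return df


def write_matrix_csv(tm: TransitionMatrix, path, provenance: Optional[dict] = None) -> Path:
    """Serialise a transition matrix as 9 CSV rows: first-choice vector + 8 rows."""
    n = tm.n_flowers
    rows = [["first_choice"] + [repr(float(x)) for x in tm.first_choice]]
    for i in range(n):
        rows.append([f"from_{i + 1}"] + [repr(float(x)) for x in tm.matrix[i]])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(
                provenance_line(
                    provenance.get("seed"), provenance.get("config_hash", ""),
                    provenance.get("version", ""),
                )
                + "\n"
            )
        fh.write("row," + ",".join(f"to_{j + 1}" for j in range(n)) + "\n")
        for r in rows:
            fh.write(",".join(r) + "\n")
    return path


def read_matrix_csv(path) -> TransitionMatrix:
    """Read a 9-row transition-matrix CSV; row sums are validated on load."""
    df = pd.read_csv(path, comment="#", index_col=0)
    if "first_choice" not in df.index:
        raise SchemaError(f"{path}: missing first_choice row")
    first = df.loc["first_choice"].to_numpy(dtype=float)
    body = df.drop(index="first_choice").to_numpy(dtype=float)
    return TransitionMatrix(matrix=body, first_choice=first)


def sequences_from_tables(
    visits: pd.DataFrame,
    bouts: Optional[pd.DataFrame] = None,
    array: Optional[FlowerArray] = None,
) -> list[VisitSequence]:
    """Assemble validated :class:`VisitSequence` objects from the visit table."""
    array = array or build_flower_array()
    durations = {}
    if bouts is not None:
        for r in bouts.itertuples(index=False):
            d = r.duration_s
            durations[(r.bee_id, int(r.bout_index))] = None if pd.isna(d) else float(d)
    out = []
    ordered = visits.sort_values(["bee_id", "bout_index", "visit_index"], kind="stable")
    for (bee_id, colony_id, bout_index, phase), grp in ordered.groupby(
        ["bee_id", "colony_id", "bout_index", "phase"], sort=True
    ):
        flowers = grp["flower_id"].tolist()
        bad = [
            (int(v), f)
            for v, f in zip(grp["visit_index"], flowers)
            if pd.isna(f) or not 1 <= int(f) <= array.n_flowers
        ]
        if bad:
            raise MalformedRecordError(
                f"bee {bee_id} bout {bout_index}: invalid flower id {bad[0][1]!r} "
                f"at visit {bad[0][0]}"
            )
        seq = VisitSequence(
            bee_id=str(bee_id),
            colony_id=str(colony_id),
            bout_index=int(bout_index),
            phase=str(phase),
            choices=[int(f) for f in flowers],
            duration_s=durations.get((bee_id, int(bout_index))),
            n_flowers=array.n_flowers,
        )
        out.append(validate_sequence(seq, array))
    if not out:
        raise MalformedRecordError("visit table contains no visits")
    return out


def write_provenance_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
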