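"""End-to-end pipeline: data → metrics → validation → inference.

The workflow mirrors the experiment's analysis plan: compute per-bout
performance statistics, compare final-training-bout performance to chance and
chance-plus-stereotypy Monte Carlo nulls, then run the AIC all-subsets
inference for the four responses on the post-exposure test bout (negative
binomial on total revisits, Cox on the first-revisit choice index, binomial on
the per-choice successes, Gaussian on log time per visit), the 5.46-mm size
split and the Kaplan–Meier curves. Everything is a pure function of the input
tables, the configuration and the seed.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import RamForageError
from .io import (
    read_table,
    sequences_from_tables,
    write_matrix_csv,
    write_provenance_json,
    write_table,
)
from .maze import build_flower_array
from .metrics import binary_choice_expansion, metrics_table
from .simulate import (
    chance_policy,
    compare_to_null,
    estimate_transition_matrix,
    monte_carlo_null,
    stereotyped_policy,
    transition_counts,
)
from .stats import (
    build_candidate_set,
    fit_binomial_glmm,
    fit_coxph,
    fit_lmm_log_time,
    fit_nb_glmm,
    kaplan_meier,
    select_and_average,
    size_split_analysis,
)
from .synth import ExperimentConfig, generate_experiment
from .transitions import contiguity_preference, vertical_bias

__all__ = ["PipelineConfig", "run_validation", "run_analyses", "run_full_pipeline"]

logger = logging.getLogger(__name__)

VALIDATION_METRICS = (
    "total_revisits",
    "correct_before_first_revisit",
    "correct_in_first_eight",
)

RESPONSES = ("revisits", "first8", "time", "survival")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; a pure function of this plus the data."""

    seed: int = 0
    out_dir: Path = Path("results")
    data_dir: Optional[Path] = None  # bees.csv / visits.csv / bouts.csv
    synth: bool = False
    synth_config: ExperimentConfig = field(default_factory=ExperimentConfig)
    n_iterations: int = 1_000_000
    averaging: str = "conditional"
    size_threshold_mm: float = 5.46
    ci_level: float = 0.95
    cox_colony: str = "none"
    responses: tuple = RESPONSES

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.synth_config.config_hash(),
            "version": __version__,
        }


class PipelineStageError(RamForageError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(name, exc) from exc
    logger.info("stage %s: done", name)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(index + 1)[index] % (2**31))


# ---------------------------------------------------------------------------
# validation stage (observed vs Monte Carlo nulls)
# ---------------------------------------------------------------------------

def run_validation(
    sequences,
    n_iterations: int = 1_000_000,
    seed: int = 0,
    allow_self: bool = True,
) -> dict:
    """Compare final-training-bout performance to the C and C+S nulls.

    Uses each bee's last training bout, estimates the pooled transition matrix
    from those bouts, runs the chance (C) and stereotyped (C+S) Monte Carlo
    simulations, and reports the observed-mean CI against each simulated mean.
    The total-revisits comparison uses complete bouts only; the other two
    metrics use all bouts. Also returns the contiguity and vertical-bias
    stereotypy diagnostics.
    """
    training = [s for s in sequences if s.phase == "training"]
    if not training:
        raise RamForageError("no training bouts to validate against")
    last_bout: dict[str, object] = {}
    for s in training:
        prev = last_bout.get(s.bee_id)
        if prev is None or s.bout_index > prev.bout_index:
            last_bout[s.bee_id] = s
    final_bouts = [last_bout[b] for b in sorted(last_bout)]
    mtab = metrics_table(final_bouts)
    n_incomplete = int((~mtab["complete"]).sum())
    if n_incomplete:
        logger.info(
            "validation: %d of %d final bouts incomplete; excluded from the "
            "total-revisits comparison", n_incomplete, len(mtab),
        )

    tm = estimate_transition_matrix(final_bouts)
    array = build_flower_array(final_bouts[0].n_flowers)
    counts, _ = transition_counts(final_bouts, array.n_flowers)
    contiguity = contiguity_preference(counts, array, allow_self=allow_self)
    vbias = vertical_bias(counts, array)

    nulls = {
        "C": monte_carlo_null(
            chance_policy(array.n_flowers, allow_self=allow_self),
            VALIDATION_METRICS, n_iterations, seed=_child_seed(seed, 0),
        ),
        "C+S": monte_carlo_null(
            stereotyped_policy(tm),
            VALIDATION_METRICS, n_iterations, seed=_child_seed(seed, 1),
        ),
    }

    rows = []
    for metric in VALIDATION_METRICS:
        obs = mtab.loc[mtab["complete"], metric] if metric == "total_revisits" else mtab[metric]
        for null_name, null in nulls.items():
            cmp_ = compare_to_null(obs, null[metric])
            rows.append(
                {
                    "metric": metric,
                    "null_model": null_name,
                    "n_observed": cmp_.n_observed,
                    "observed_mean": cmp_.observed_mean,
                    "ci_low": cmp_.ci_low,
                    "ci_high": cmp_.ci_high,
                    "simulated_mean": cmp_.null_mean,
                    "null_inside_ci": cmp_.null_inside_ci,
                    "direction": cmp_.direction,
                }
            )
    return {
        "comparison": pd.DataFrame(rows),
        "transition_matrix": tm,
        "contiguity": contiguity,
        "vertical_bias": vbias,
        "final_bout_metrics": mtab,
    }


# ---------------------------------------------------------------------------
# inference stage
# ---------------------------------------------------------------------------

def build_analysis_frames(sequences, bees: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-response analysis tables for the post-exposure test bout."""
    test = [s for s in sequences if s.phase == "test"]
    if not test:
        raise RamForageError("no test-phase bouts found")
    mtab = metrics_table(test)
    bee_cols = bees.rename(
        columns={"colony_id": "colony", "thorax_width_mm": "size"}
    )[["bee_id", "colony", "size", "treatment"]]
    merged = mtab.merge(bee_cols, on="bee_id", how="inner", validate="one_to_one")

    frames = {"revisits": merged.copy(), "time": merged.dropna(subset=["time_per_visit_s"]).copy()}
    n_no_time = len(merged) - len(frames["time"])
    if n_no_time:
        logger.info("time-per-visit analysis: dropped %d bees without duration", n_no_time)

    long_rows = []
    dropped_short = 0
    bee_info = {r.bee_id: r for r in merged.itertuples(index=False)}
    for s in test:
        expansion = binary_choice_expansion(s)
        if expansion is None:
            dropped_short += 1
            continue
        info = bee_info[s.bee_id]
        for choice_idx, success in enumerate(expansion, start=1):
            long_rows.append(
                {
                    "bee_id": s.bee_id,
                    "colony": info.colony,
                    "treatment": info.treatment,
                    "size": info.size,
                    "choice_index": choice_idx,
                    "success": success,
                }
            )
    if dropped_short:
        logger.info("first-eight analysis: dropped %d bouts shorter than 8 visits", dropped_short)
    frames["first8"] = pd.DataFrame(long_rows)

    surv = merged.rename(columns={"survival_time": "time", "survival_event": "event"})[
        ["bee_id", "colony", "treatment", "size", "time", "event"]
    ]
    frames["survival"] = surv
    return frames


def _fit_candidates(frame: pd.DataFrame, response: str, cox_colony: str = "none"):
    if response == "revisits":
        specs = build_candidate_set("total_revisits", "nb")
        return [fit_nb_glmm(frame, s, response_col="total_revisits", group_col="colony") for s in specs]
    if response == "first8":
        specs = build_candidate_set("success", "binomial")
        return [fit_binomial_glmm(frame, s) for s in specs]
    if response == "time":
        specs = build_candidate_set("time_per_visit_s", "gaussian_log")
        return [fit_lmm_log_time(frame, s, group_col="colony") for s in specs]
    if response == "survival":
        specs = build_candidate_set("first_revisit", "coxph")
        return [fit_coxph(frame, s, colony=cox_colony) for s in specs]
    raise ValueError(f"unknown response {response!r}")


def run_analyses(
    frames: dict[str, pd.DataFrame],
    responses=RESPONSES,
    averaging: str = "conditional",
    cox_colony: str = "none",
    ci_level: float = 0.95,
) -> dict[str, dict]:
    """All-subsets selection + averaging for each requested response."""
    out = {}
    for response in responses:
        fits = _fit_candidates(frames[response], response, cox_colony=cox_colony)
        table, averaged = select_and_average(fits, mode=averaging, level=ci_level)
        out[response] = {"fits": fits, "selection": table, "averaged": averaged}
        logger.info("response %s: best model %s", response, table.best_model)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_full_pipeline(config: PipelineConfig) -> dict:
    """Generate-or-load data, then run every analysis stage, writing CSVs.

    Returns a dict with the in-memory results and the output directory.
    Output files: bees/visits/bouts (when synthesising), metrics.csv,
    validation_comparison.csv, transition_matrix.csv, stereotypy_pairs.csv,
    <response>_selection.csv / <response>_averaged.csv, size_split.csv,
    km_curves.csv and provenance.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    with _stage("data"):
        if config.synth:
            dataset = generate_experiment(config.synth_config, seed=_child_seed(config.seed, 2))
            bees, visits, bouts = dataset.bees, dataset.visits, dataset.bouts
            write_table(bees, out_dir / "bees.csv", prov)
            write_table(visits, out_dir / "visits.csv", prov)
            write_table(bouts, out_dir / "bouts.csv", prov)
        else:
            if config.data_dir is None:
                raise RamForageError("either synth=True or a data_dir is required")
            data_dir = Path(config.data_dir)
            bees = read_table(data_dir / "bees.csv", "bees")
            visits = read_table(data_dir / "visits.csv", "visits")
            bouts = read_table(data_dir / "bouts.csv", "bouts")
        sequences = sequences_from_tables(visits, bouts)

    with _stage("metrics"):
        mtab = metrics_table(sequences)
        write_table(mtab, out_dir / "metrics.csv", prov)

    with _stage("validation"):
        validation = run_validation(
            sequences, n_iterations=config.n_iterations, seed=config.seed
        )
        write_table(validation["comparison"], out_dir / "validation_comparison.csv", prov)
        write_matrix_csv(validation["transition_matrix"], out_dir / "transition_matrix.csv", prov)
        write_table(validation["vertical_bias"].pairs, out_dir / "stereotypy_pairs.csv", prov)

    with _stage("analysis"):
        frames = build_analysis_frames(sequences, bees)
        analyses = run_analyses(
            frames,
            responses=config.responses,
            averaging=config.averaging,
            cox_colony=config.cox_colony,
            ci_level=config.ci_level,
        )
        for response, result in analyses.items():
            write_table(result["selection"].table, out_dir / f"{response}_selection.csv", prov)
            write_table(result["averaged"], out_dir / f"{response}_averaged.csv", prov)

    with _stage("size_split"):
        split = size_split_analysis(
            frames["revisits"],
            lambda df, spec: fit_nb_glmm(df, spec, response_col="total_revisits", group_col="colony"),
            threshold_mm=config.size_threshold_mm,
            level=config.ci_level,
        )
        write_table(split, out_dir / "size_split.csv", prov)

    with _stage("kaplan_meier"):
        km = kaplan_meier(frames["survival"])
        write_table(km, out_dir / "km_curves.csv", prov)

    with _stage("provenance"):
        vb = validation["vertical_bias"]
        write_provenance_json(
            out_dir / "provenance.json",
            {
                **prov,
                "n_bees": int(len(bees)),
                "n_bouts": int(len(bouts)),
                "n_iterations": config.n_iterations,
                "averaging": config.averaging,
                "cox_colony": config.cox_colony,
                "contiguity_observed": validation["contiguity"].observed_proportion,
                "contiguity_expected": validation["contiguity"].expected_proportion,
                "vertical_bias_rho": vb.rho,
            },
        )

    return {
        "out_dir": out_dir,
        "bees": bees,
        "sequences": sequences,
        "metrics": mtab,
        "validation": validation,
        "frames": frames,
        "analyses": analyses,
        "size_split": split,
        "km": km,
    }
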