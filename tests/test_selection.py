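"""AIC selection arithmetic, Wald/hazard-ratio intervals, model averaging."""

import numpy as np
import pandas as pd
import pytest

from ramforage.errors import RamForageError
from ramforage.stats import (
    akaike_weights,
    build_candidate_set,
    hazard_ratio,
    select_and_average,
    size_split_analysis,
    wald_ci,
    fit_nb_glmm,
)
from ramforage.stats.models import FitResult, ModelSpec


class TestAkaikeWeights:
    def test_selection_table_total_revisits(self):
        """Five-candidate count-model selection: ΔAIC → weights at 3 dp."""
        # weights depend only on AIC differences, so the ΔAIC column is the input
        tab = akaike_weights(
            [0.0, 2.18, 2.36, 4.03, 4.22],
            ["treatment*size", "treatment", "basic", "treatment+size", "size"],
        ).table
        np.testing.assert_allclose(
            tab["weight"].round(3), [0.527, 0.177, 0.162, 0.070, 0.064], atol=1e-9
        )
        assert tab["in_best_set"].tolist() == [True, False, False, False, False]

    def test_selection_table_first_revisit(self):
        """Survival-model selection: three models fall inside the 2-unit set."""
        tab = akaike_weights(
            [0.0, 0.79, 1.81, 2.51, 5.11],
            ["treatment", "basic", "treatment+size", "size", "treatment*size"],
        ).table
        np.testing.assert_allclose(
            tab["weight"].round(3), [0.410, 0.276, 0.166, 0.117, 0.032], atol=1e-9
        )
        assert tab["in_best_set"].tolist() == [True, True, True, False, False]

    def test_single_model_gets_full_weight(self):
        tab = akaike_weights([123.4], ["only"]).table
        assert tab["weight"].iloc[0] == 1.0

    def test_weights_sum_to_one_and_best_is_heaviest(self, rng):
        for _ in range(50):
            aics = rng.uniform(100, 140, size=rng.integers(2, 8))
            tab = akaike_weights(aics).table
            assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
            assert tab["delta_aic"].iloc[0] == 0.0
            assert tab["weight"].iloc[0] == tab["weight"].max()

    def test_nonfinite_aics_dropped(self):
        tab = akaike_weights([100.0, np.inf, np.nan, 101.0]).table
        assert len(tab) == 2

    def test_all_nonfinite_raises(self):
        with pytest.raises(RamForageError):
            akaike_weights([np.nan, np.inf])


class TestWaldAndHazard:
    def test_wald_interval_strong_negative_coefficient(self):
        lo, hi = wald_ci(-11.010, 4.471)
        assert (round(lo, 3), round(hi, 3)) == (-19.773, -2.247)

    def test_wald_interval_interaction(self):
        lo, hi = wald_ci(2.084, 0.810)
        assert (round(lo, 3), round(hi, 3)) == (0.496, 3.672)

    def test_wald_degenerate(self):
        assert wald_ci(1.5, 0.0) == (1.5, 1.5)

    def test_hazard_ratio_high_dose(self):
        hr, lo, hi = hazard_ratio(0.8295, 0.3937)
        assert (round(hr, 3), round(lo, 3), round(hi, 3)) == (2.292, 1.060, 4.959)

    def test_hazard_ratio_low_dose(self):
        hr, lo, hi = hazard_ratio(0.8353, 0.3811)
        assert (round(hr, 3), round(lo, 3), round(hi, 3)) == (2.306, 1.092, 4.866)

    def test_null_hazard_ratio(self):
        assert hazard_ratio(0.0, 0.1)[0] == 1.0

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, -1.0)


def make_fit(name, aic_target, params, ses, family="nb", fixed=("treatment",)):
    spec = ModelSpec(response="y", family=family, fixed=fixed, name=name)
    k = len(params)
    loglik = -(aic_target - 2 * k) / 2
    return FitResult(
        spec=spec,
        loglik=loglik,
        k=k,
        params=pd.Series(params),
        bse=pd.Series(ses),
        converged=True,
        n_obs=50,
    )


class TestSelectAndAverage:
    def test_dominant_model_passes_through(self):
        fits = [
            make_fit("treatment*size", 100.0, {"intercept": 1.0, "b": 2.0}, {"intercept": 0.1, "b": 0.2}),
            make_fit("basic", 104.0, {"intercept": 0.5}, {"intercept": 0.1}),
        ]
        table, avg = select_and_average(fits)
        assert table.best_set == ["treatment*size"]
        row = avg.set_index("coefficient").loc["b"]
        assert row["estimate"] == 2.0 and row["se"] == 0.2
        assert row["averaging"] == "single-best"

    def test_two_identical_models_average_to_common_value(self):
        fits = [
            make_fit("treatment", 100.0, {"b": 1.5}, {"b": 0.3}),
            make_fit("treatment+size", 100.0, {"b": 1.5}, {"b": 0.3}),
        ]
        _, avg = select_and_average(fits)
        row = avg.set_index("coefficient").loc["b"]
        assert row["estimate"] == pytest.approx(1.5)
        assert row["se"] == pytest.approx(0.3)

    def test_three_model_best_set_is_averaged(self):
        """AIC pattern with three models inside two units averages exactly those."""
        fits = [
            make_fit("treatment", 384.7, {"b": 0.9}, {"b": 0.4}),
            make_fit("basic", 385.49, {"intercept": 0.1}, {"intercept": 0.2}),
            make_fit("treatment+size", 386.51, {"b": 0.7, "size": 0.2}, {"b": 0.45, "size": 0.4}),
            make_fit("size", 387.21, {"size": 0.3}, {"size": 0.4}),
            make_fit("treatment*size", 389.81, {"b": 0.8, "size": 0.2, "bs": 0.1}, {"b": 0.5, "size": 0.4, "bs": 0.3}),
        ]
        table, avg = select_and_average(fits)
        assert table.best_set == ["treatment", "basic", "treatment+size"]
        row = avg.set_index("coefficient").loc["b"]
        # conditional averaging: only the two treatment models carry "b"
        w = np.exp(-np.array([0.0, 1.81]) / 2)
        w = w / w.sum()
        b_bar = w[0] * 0.9 + w[1] * 0.7
        assert row["estimate"] == pytest.approx(b_bar, abs=1e-9)
        se_expected = np.sum(
            w * np.sqrt(np.array([0.4, 0.45]) ** 2 + (np.array([0.9, 0.7]) - b_bar) ** 2)
        )
        assert row["se"] == pytest.approx(se_expected, abs=1e-9)
        assert row["averaging"] == "conditional"

    def test_full_averaging_shrinks_toward_zero(self):
        fits = [
            make_fit("treatment", 100.0, {"b": 1.0}, {"b": 0.2}),
            make_fit("basic", 100.5, {"intercept": 0.0}, {"intercept": 0.1}),
        ]
        _, cond = select_and_average(fits, mode="conditional")
        _, full = select_and_average(fits, mode="full")
        b_cond = cond.set_index("coefficient").loc["b", "estimate"]
        b_full = full.set_index("coefficient").loc["b", "estimate"]
        assert b_cond == pytest.approx(1.0)
        assert 0.0 < b_full < b_cond

    def test_nonconverged_fits_excluded(self):
        good = make_fit("basic", 100.0, {"intercept": 0.2}, {"intercept": 0.1})
        bad = make_fit("treatment", 90.0, {"b": 25.0}, {"b": 40.0})
        bad.converged = False
        table, _ = select_and_average([good, bad])
        assert table.best_model == "basic"

    def test_cox_fits_report_hazard_ratios(self):
        fits = [make_fit("treatment", 50.0, {"b": 0.8295}, {"b": 0.3937}, family="coxph")]
        _, avg = select_and_average(fits)
        row = avg.set_index("coefficient").loc["b"]
        assert round(row["hazard_ratio"], 3) == 2.292
        assert round(row["hr_ci_low"], 3) == 1.060


class TestSizeSplit:
    @staticmethod
    def fit_fn(df, spec):
        return fit_nb_glmm(df, spec, response_col="total_revisits", group_col="colony")

    def make_data(self, rng, n=80, effect_large_only=True):
        size = rng.uniform(4.6, 6.1, size=n)
        treatment = np.where(np.arange(n) % 2 == 0, "control", "high")
        mu = np.exp(
            0.3 + np.where((treatment == "high") & ((size > 5.46) | (not effect_large_only)), 1.6, 0.0)
        )
        return pd.DataFrame(
            {
                "size": size,
                "treatment": treatment,
                "colony": [f"c{i % 5}" for i in range(n)],
                "total_revisits": rng.poisson(mu),
            }
        )

    def test_strata_sizes_and_effect_localisation(self, rng):
        df = self.make_data(rng)
        res = size_split_analysis(df, self.fit_fn)
        per = res.drop_duplicates("stratum").set_index("stratum")
        assert per.loc["small", "n_bees"] + per.loc["large", "n_bees"] == len(df)
        assert (
            per.loc["large", "delta_aic_treatment_vs_basic"]
            > per.loc["small", "delta_aic_treatment_vs_basic"]
        )

    def test_single_stratum_with_warning(self, rng):
        df = self.make_data(rng)
        df["size"] = 5.0  # everyone small
        res = size_split_analysis(df, self.fit_fn)
        assert set(res["stratum"]) == {"small"}
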