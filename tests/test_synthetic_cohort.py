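"""Log-normal quantile fitting, score inversion and the calibrated
synthetic cohort generator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wealthproxy import (
    EconomicConfig,
    GeneratorConfig,
    fit_lognormal_from_quantiles,
    generate_cohort,
    invert_income_to_score,
    score_to_monthly_inr,
)
from wealthproxy.synthetic_cohort import (
    COHORT_QUANTILES,
    Z75,
    BundleSynthesizer,
)
from wealthproxy.iwi_scoring import compute_iwi_score


class TestQuantileFit:
    def test_symmetric_quartet_closed_form(self):
        spec = fit_lognormal_from_quantiles(1.0, 0.5, 2.0)
        assert spec.mu == 0.0
        assert spec.sigma == pytest.approx(math.log(4) / (2 * Z75), rel=1e-15)
        # symmetric quartets round-trip all three quantiles exactly
        assert spec.q1 == pytest.approx(0.5, rel=1e-12)
        assert spec.q3 == pytest.approx(2.0, rel=1e-12)

    def test_cohort_income_quartet(self):
        spec = fit_lognormal_from_quantiles(17350.0, 10000.0, 40000.0)
        assert spec.mu == pytest.approx(math.log(17350.0), rel=1e-15)
        assert spec.sigma == pytest.approx(math.log(4.0) / (2 * Z75),
                                           rel=1e-15)
        assert spec.median == pytest.approx(17350.0, rel=1e-12)

    @given(median=st.floats(min_value=1e2, max_value=1e6),
           spread=st.floats(min_value=1.1, max_value=10.0))
    def test_round_trip_is_exact_for_log_symmetric_inputs(self, median,
                                                          spread):
        spec = fit_lognormal_from_quantiles(median, median / spread,
                                            median * spread)
        assert spec.median == pytest.approx(median, rel=1e-12)
        assert spec.q1 == pytest.approx(median / spread, rel=1e-12)
        assert spec.q3 == pytest.approx(median * spread, rel=1e-12)

    @pytest.mark.parametrize("quartet", [
        (10.0, 10.0, 10.0),   # degenerate spread
        (10.0, 12.0, 20.0),   # q1 above median
        (10.0, -1.0, 20.0),   # negative quantile
        (0.0, 1.0, 2.0),
    ])
    def test_invalid_quantiles_rejected(self, quartet):
        with pytest.raises(ValueError):
            fit_lognormal_from_quantiles(*quartet)


class TestScoreInversion:
    def test_round_trip_recovers_score(self, econ):
        income = score_to_monthly_inr(50.0, econ)
        assert invert_income_to_score(income, econ) == pytest.approx(
            50.0, abs=1e-9)

    def test_income_below_floor_clamps_to_zero_with_warning(self, econ):
        floor_income = score_to_monthly_inr(0.0, econ)
        with pytest.warns(UserWarning, match="clamped"):
            assert invert_income_to_score(floor_income / 10, econ) == 0.0

    def test_monotone_in_income(self, econ):
        incomes = np.geomspace(1e2, 1e6, 50)
        scores = invert_income_to_score(incomes, econ)
        assert np.all(np.diff(scores) >= 0)

    def test_non_positive_income_rejected(self, econ):
        with pytest.raises(ValueError):
            invert_income_to_score(0.0, econ)


class TestBundleSynthesis:
    def test_bundle_score_matches_recomputation(self, weight_table):
        synthesizer = BundleSynthesizer(weight_table)
        for target in (0.0, 12.5, 40.0, 73.3, 100.0):
            assets, realized = synthesizer.bundle(target)
            assert compute_iwi_score(assets, weight_table) == pytest.approx(
                realized, abs=1e-9)

    def test_extreme_targets_hit_extreme_bundles(self, weight_table):
        synthesizer = BundleSynthesizer(weight_table)
        _, low = synthesizer.bundle(0.0)
        _, high = synthesizer.bundle(100.0)
        assert low == pytest.approx(0.0, abs=1e-4)
        assert high == pytest.approx(100.0, abs=1e-4)

    @given(target=st.floats(min_value=0.0, max_value=100.0))
    def test_realized_score_close_to_target(self, weight_table, target):
        synthesizer = BundleSynthesizer(weight_table)
        _, realized = synthesizer.bundle(target)
        assert abs(realized - target) <= 5.0


class TestGenerator:
    def test_seeded_runs_are_bit_reproducible(self):
        gen = GeneratorConfig(n=15, seed=11)
        records_a, truth_a = generate_cohort(gen)
        records_b, truth_b = generate_cohort(gen)
        assert records_a == records_b
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_different_seeds_differ(self):
        _, truth_a = generate_cohort(GeneratorConfig(n=15, seed=1))
        _, truth_b = generate_cohort(GeneratorConfig(n=15, seed=2))
        assert not truth_a["income_self"].equals(truth_b["income_self"])

    def test_perfect_correlation_gives_comonotone_channels(self):
        gen = GeneratorConfig(
            n=50, seed=3, selection_noise_sigma=0.0,
            latent_correlations={"self": 1.0, "iwi": 1.0, "gapminder": 1.0,
                                 "oop": 1.0},
            n_missing_iwi=0, n_missing_gapminder=0)
        _, truth = generate_cohort(gen)
        rank = lambda column: truth[column].rank().to_numpy()
        base = rank("income_self")
        for column in ("target_income_iwi", "target_income_gapminder",
                       "oop_total"):
            np.testing.assert_array_equal(rank(column), base)

    def test_default_missingness_mirrors_study_completion(self):
        records, truth = generate_cohort(GeneratorConfig(n=226, seed=5))
        assert sum(r.assets is None for r in records) == 1
        assert sum(r.selection is None for r in records) == 1
        assert truth["iwi_missing"].sum() == 1
        assert truth["gapminder_missing"].sum() == 1

    def test_demographic_frequencies_roughly_respected(self):
        records, _ = generate_cohort(GeneratorConfig(n=2000, seed=9))
        male = sum(r.demographics["sex"] == "male" for r in records) / 2000
        assert male == pytest.approx(143 / 226, abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n=0)
        with pytest.raises(ValueError):
            GeneratorConfig(latent_correlations={"self": 2.0, "iwi": 1.0,
                                                 "gapminder": 1.0,
                                                 "oop": 0.3})

    def test_marginal_calibration_at_moderate_scale(self, econ):
        """Realized channel medians match the fitted targets: 2% for the
        continuous channels, 10% for the discretized ones."""
        records, truth = generate_cohort(GeneratorConfig(n=20000, seed=17))
        targets = {k: COHORT_QUANTILES[k][0] for k in COHORT_QUANTILES}
        assert np.median(truth["income_self"]) == pytest.approx(
            targets["self"], rel=0.02)
        assert np.median(truth["oop_total"]) == pytest.approx(
            targets["oop"], rel=0.02)
        realized_iwi = score_to_monthly_inr(
            truth["realized_score_iwi"].to_numpy(), econ)
        assert np.median(realized_iwi) == pytest.approx(
            targets["iwi"], rel=0.10)

    def test_score_recovery_within_five_points(self, small_cohort):
        _, truth = small_cohort
        err = (truth["realized_score_iwi"]
               - truth["target_score_iwi"]).abs()
        assert (err <= 5.0).mean() >= 0.90
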