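"""Descriptive statistics, relative-to-muscle distribution, rank matrices, BCI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ecotransfer.datamodel import CohortDataset, Measurement, ValidationError
from ecotransfer.summaries import (
    EmptySummaryError,
    compute_bci,
    relative_to_muscle,
    spearman_matrix,
    summarize,
)

from conftest import make_animal


class TestSummarize:
    def test_constant_vector(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s.am == s.median == 5.0
        assert s.gm == pytest.approx(5.0)
        assert s.sd == 0.0

    def test_hand_computed_example(self):
        s = summarize([1.0, 10.0, 100.0])
        assert s.gm == pytest.approx(10.0)
        assert s.am == pytest.approx(37.0)
        assert s.median == 10.0
        assert (s.min, s.max) == (1.0, 100.0)

    def test_censored_values_counted_but_excluded(self):
        s = summarize([1.0, 10.0, 100.0, 999.0], [False, False, False, True])
        assert s.n_censored == 1 and s.n_detected == 3
        # statistics unchanged by the censored magnitude
        assert s.am == pytest.approx(37.0) and s.max == 100.0

    def test_half_lod_policy_substitutes_half_threshold(self):
        s = summarize([4.0, 8.0], [True, False], policy="half_lod")
        assert s.am == pytest.approx((2.0 + 8.0) / 2)

    def test_all_censored_raises(self):
        with pytest.raises(EmptySummaryError):
            summarize([1.0], [True])

    def test_even_n_median_is_midpoint(self):
        assert summarize([1.0, 2.0, 3.0, 10.0]).median == 2.5

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=12))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_gm_never_exceeds_am(self, values):
        s = summarize(values)
        assert s.gm <= s.am * (1 + 1e-9)


class TestRelativeToMuscle:
    def test_tissue_equal_to_muscle_gives_100(self, tiny_cohort):
        ms = [
            Measurement(m.animal_id, "liver", "Cs137", next(
                x.value for x in tiny_cohort.measurements
                if x.animal_id == m.animal_id and x.tissue == "muscle"
            ), "Bq/kg", "dry")
            for m in tiny_cohort.measurements if m.tissue == "muscle"
        ]
        ds = tiny_cohort.with_measurements(list(tiny_cohort.measurements) + ms)
        rel = relative_to_muscle(ds, "Cs137")
        assert rel["liver"].per_animal_percent == (100.0, 100.0, 100.0)
        assert rel["muscle"].mean_percent == 100.0

    def test_hand_computed_three_animal_fixture(self, tiny_cohort):
        rel = relative_to_muscle(tiny_cohort, "Cs137")
        # heart/muscle: 20/40, 8/10, 5/20 -> 50%, 80%, 25% -> mean 51.666%
        assert rel["heart"].per_animal_percent == pytest.approx((50.0, 80.0, 25.0))
        assert rel["heart"].mean_percent == pytest.approx(155.0 / 3)

    def test_scale_free_per_animal(self, tiny_cohort):
        scaled = [
            Measurement(m.animal_id, m.tissue, m.analyte,
                        m.value * (7.0 if m.animal_id == "W2" else 1.0),
                        m.unit, m.basis, m.censored)
            for m in tiny_cohort.measurements
        ]
        rel0 = relative_to_muscle(tiny_cohort, "Cs137")
        rel1 = relative_to_muscle(tiny_cohort.with_measurements(scaled), "Cs137")
        assert rel1["heart"].per_animal_percent == pytest.approx(
            rel0["heart"].per_animal_percent
        )

    def test_no_muscle_values_raises(self, tiny_cohort):
        only_heart = [m for m in tiny_cohort.measurements if m.tissue == "heart"]
        with pytest.raises(ValidationError):
            relative_to_muscle(tiny_cohort.with_measurements(only_heart), "Cs137")


class TestSpearmanMatrix:
    def _cohort(self, muscle, liver):
        animals = [make_animal(f"W{i}") for i in range(len(muscle))]
        ms = []
        for a, mv, lv in zip(animals, muscle, liver):
            ms.append(Measurement(a.animal_id, "muscle", "Cd", mv, "ug/kg", "dry"))
            ms.append(Measurement(a.animal_id, "liver", "Cd", lv, "ug/kg", "dry"))
        return CohortDataset(animals, ms)

    def test_perfect_monotone_pairs(self):
        up = self._cohort([1, 2, 3, 4], [10, 20, 30, 40])
        assert spearman_matrix(up, "Cd").loc["muscle", "liver"] == pytest.approx(1.0)
        down = self._cohort([1, 2, 3, 4], [8, 6, 4, 2])
        assert spearman_matrix(down, "Cd").loc["muscle", "liver"] == pytest.approx(-1.0)

    def test_matches_pearson_of_midranks_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 4, size=8).astype(float)  # ties guaranteed
            y = rng.integers(0, 4, size=8).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            ds = self._cohort(x, y)
            got = spearman_matrix(ds, "Cd").loc["muscle", "liver"]
            expect = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(7) * 10, rng.random(7) * 10
        base = spearman_matrix(self._cohort(x, y), "Cd").loc["muscle", "liver"]
        trans = spearman_matrix(self._cohort(np.exp(x), y), "Cd").loc["muscle", "liver"]
        assert trans == pytest.approx(base, abs=1e-12)

    def test_fewer_than_three_pairs_is_missing(self):
        ds = self._cohort([1, 2], [3, 4])
        assert np.isnan(spearman_matrix(ds, "Cd").loc["muscle", "liver"])


class TestBci:
    REF = np.array([[100.0, 20.0], [110.0, 24.0], [120.0, 26.0], [130.0, 32.0]])

    def test_hand_fitted_four_point_reference(self):
        # slope 0.38, intercept -18.2 by manual least squares
        bci = compute_bci(self.REF[:, 1], self.REF[:, 0], self.REF)
        assert bci == pytest.approx([0.2, 0.4, -1.4, 0.8], abs=1e-9)

    def test_reference_residuals_sum_to_zero(self):
        bci = compute_bci(self.REF[:, 1], self.REF[:, 0], self.REF)
        assert abs(bci.sum()) < 1e-9

    def test_animal_on_the_line_has_zero_bci(self):
        # point exactly on mass = 0.38 * length - 18.2
        assert compute_bci([0.38 * 115 - 18.2], [115.0], self.REF)[0] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_missing_biometric_gives_nan(self):
        out = compute_bci([np.nan, 25.0], [120.0, 118.0], self.REF)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_constant_length_reference_rejected(self):
        with pytest.raises(ValidationError):
            compute_bci([20.0], [100.0], [[100, 20], [100, 22], [100, 24]])
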