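"""Tm-shift statistics, hit filters, and the shift density."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cetsakit import (
    HitThresholds,
    ValidationError,
    call_hits,
    delta_tm,
    replicate_shift_test,
    shift_results,
    tm_shift_density,
)
from cetsakit.fit import BoltzmannFit
from cetsakit.synthetic import MeltParams

from .oracles import one_sample_t_pvalue_n3


def make_fit(tm, tm_defined=True, r=0.95):
    return BoltzmannFit(params=MeltParams(tm, 2.0, 0.0), tm=tm, tm_defined=tm_defined,
                        sse=0.0, r=r, rmse=0.0,
                        grid_params=MeltParams(tm, 2.0, 0.0), grid_sse=0.0)


def fits_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "condition", "replicate",
                                       "tm", "tm_defined", "r"])


class TestDeltaTm:
    def test_stabilization_magnitude(self):
        # the headline-scale shift: 63.75 - 50.00
        assert delta_tm(make_fit(63.75), make_fit(50.0)) == pytest.approx(13.75)

    def test_identical_fits_zero(self):
        assert delta_tm(make_fit(50.0), make_fit(50.0)) == 0.0

    def test_destabilization_sign(self):
        assert delta_tm(make_fit(48.0), make_fit(50.0)) == pytest.approx(-2.0)

    def test_undefined_tm_gives_nan(self):
        assert math.isnan(delta_tm(make_fit(50.0, tm_defined=False), make_fit(50.0)))


class TestReplicateShiftTest:
    def test_exact_null(self):
        assert replicate_shift_test([0.0, 0.0, 0.0]) == 1.0

    def test_closed_form_t_pvalue(self):
        assert replicate_shift_test([2.0, 3.0, 4.0]) == pytest.approx(
            one_sample_t_pvalue_n3([2.0, 3.0, 4.0]), abs=1e-9)
        assert replicate_shift_test([2.0, 3.0, 4.0]) == pytest.approx(0.0351, abs=2e-4)

    def test_zero_variance_nonzero_mean(self):
        assert replicate_shift_test([5.0, 5.0, 5.0]) == 0.0

    def test_not_testable_below_two(self):
        assert math.isnan(replicate_shift_test([1.0]))
        assert math.isnan(replicate_shift_test([1.0, float("nan")]))

    def test_permutation_alternative(self):
        # all-positive triple: only the all-plus and all-minus sign patterns
        # reach |mean| >= observed -> p = 2/8
        assert replicate_shift_test([2.0, 3.0, 4.0], method="permutation") == pytest.approx(0.25)


class TestCallHits:
    def base_results(self, **overrides):
        row = {"protein_id": "P1", "delta_tm_rep1": 3.1, "delta_tm_rep2": 2.8,
               "delta_tm_rep3": 3.3, "mean_delta_tm": 3.07, "n_replicates": 3,
               "p_value": 0.005, "min_fit_r": 0.92, "sign_consistent": True,
               "q_value": 0.01}
        row.update(overrides)
        return pd.DataFrame([row])

    def test_all_criteria_met(self):
        hits = call_hits(self.base_results())
        assert hits["is_hit"].all()

    def test_low_correlation_blocks(self):
        assert not call_hits(self.base_results(min_fit_r=0.65))["is_hit"].any()

    def test_boundary_correlation_excluded(self):
        # "above 0.7" is strict
        assert not call_hits(self.base_results(min_fit_r=0.7))["is_hit"].any()

    def test_high_pvalue_blocks(self):
        assert not call_hits(self.base_results(p_value=0.02))["is_hit"].any()

    def test_sign_inconsistency_blocks(self):
        assert not call_hits(self.base_results(sign_consistent=False))["is_hit"].any()

    def test_sorted_by_absolute_shift(self):
        results = pd.concat([self.base_results(),
                             self.base_results(protein_id="P2", mean_delta_tm=-8.0)],
                            ignore_index=True)
        out = call_hits(results)
        assert list(out["protein_id"]) == ["P2", "P1"]

    def test_empty_input(self):
        out = call_hits(pd.DataFrame())
        assert out.empty and "is_hit" in out.columns

    def test_filter_monotonicity(self):
        results = pd.concat(
            [self.base_results(protein_id=f"P{i}", p_value=p, min_fit_r=r)
             for i, (p, r) in enumerate([(0.001, 0.95), (0.009, 0.75),
                                         (0.02, 0.9), (0.005, 0.71)])],
            ignore_index=True)
        loose = call_hits(results, HitThresholds(r_threshold=0.7, p_threshold=0.01))
        strict_r = call_hits(results, HitThresholds(r_threshold=0.9, p_threshold=0.01))
        strict_p = call_hits(results, HitThresholds(r_threshold=0.7, p_threshold=0.002))
        loose_set = set(loose.loc[loose.is_hit, "protein_id"])
        assert set(strict_r.loc[strict_r.is_hit, "protein_id"]) <= loose_set
        assert set(strict_p.loc[strict_p.is_hit, "protein_id"]) <= loose_set


class TestShiftResults:
    def test_pairs_replicates_and_aggregates(self):
        fits = fits_frame([
            ("P1", "vehicle", 1, 50.0, True, 0.99), ("P1", "treated", 1, 53.0, True, 0.98),
            ("P1", "vehicle", 2, 50.5, True, 0.97), ("P1", "treated", 2, 53.2, True, 0.96),
        ])
        out = shift_results(fits)
        row = out.iloc[0]
        assert row["delta_tm_rep1"] == pytest.approx(3.0)
        assert row["mean_delta_tm"] == pytest.approx((3.0 + 2.7) / 2)
        assert row["min_fit_r"] == pytest.approx(0.96)
        assert row["sign_consistent"]

    def test_undefined_tm_replicate_excluded(self):
        fits = fits_frame([
            ("P1", "vehicle", 1, 50.0, True, 0.99), ("P1", "treated", 1, 53.0, True, 0.98),
            ("P1", "vehicle", 2, float("nan"), False, 0.5), ("P1", "treated", 2, 53.0, True, 0.9),
        ])
        out = shift_results(fits)
        assert out.iloc[0]["n_replicates"] == 1
        assert math.isnan(out.iloc[0]["p_value"])  # single replicate is not testable

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(10):
            for rep in (1, 2, 3):
                rows.append((f"P{i}", "vehicle", rep, 50 + rng.normal(0, 1), True, 0.95))
                rows.append((f"P{i}", "treated", rep, 52 + rng.normal(0, 1), True, 0.95))
        fits = fits_frame(rows)
        forward = shift_results(fits).set_index("protein_id")
        swapped = shift_results(fits, vehicle="treated", treated="vehicle").set_index("protein_id")
        np.testing.assert_allclose(swapped["mean_delta_tm"], -forward["mean_delta_tm"])
        np.testing.assert_allclose(swapped["p_value"], forward["p_value"], atol=1e-12)


class TestShiftDensity:
    def test_symmetric_about_zero(self):
        density = tm_shift_density(np.zeros(10), bandwidth=1.0)
        peak = density.grid[np.argmax(density.density)]
        assert peak == pytest.approx(0.0, abs=0.05)
        np.testing.assert_allclose(density.density, density.density[::-1], atol=1e-12)

    @given(st.integers(0, 1000))
    def test_integrates_to_one(self, seed):
        x = np.random.default_rng(seed).normal(0, 2, 50)
        density = tm_shift_density(x)
        assert np.trapezoid(density.density, density.grid) == pytest.approx(1.0, abs=1e-3)

    def test_translation_equivariance(self):
        x = np.array([-1.0, 0.5, 2.0, 3.5, 0.1])
        d0 = tm_shift_density(x, bandwidth=1.0)
        d2 = tm_shift_density(x + 2.0, bandwidth=1.0)
        mode0 = d0.grid[np.argmax(d0.density)]
        mode2 = d2.grid[np.argmax(d2.density)]
        assert mode2 - mode0 == pytest.approx(2.0, abs=1e-9)

    def test_degenerate_fallback(self):
        density = tm_shift_density([1.5, 1.5, 1.5])
        assert density.degenerate
        assert density.bandwidth == 0.1

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            tm_shift_density([1.0])
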