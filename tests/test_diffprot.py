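"""Global-proteome statistics: ratios, weighting, z-scores, t-test, enrichment."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cetsakit import (
    GeneSetCollection,
    NumericalError,
    ValidationError,
    aggregate_weighted,
    estimate_inverse_variance_weights,
    hypergeometric_enrichment,
    log2_ratio_to_control,
    read_gmt,
    spectrum_ratio_table,
    standardize_zscores,
    ttest_proteins,
)

from .oracles import hypergeom_tail_enumeration, pooled_two_sample_t


class TestLog2Ratio:
    def series(self, values):
        return pd.Series(values, index=[f"ch{i}" for i in range(len(values))])

    def test_equal_to_control_mean_is_zero(self):
        s = self.series([100.0, 100.0, 100.0])
        out = log2_ratio_to_control(s, ["ch0", "ch1"])
        assert out["ch2"] == pytest.approx(0.0)

    def test_double_control_mean_is_one(self):
        s = self.series([100.0, 100.0, 200.0])
        assert log2_ratio_to_control(s, ["ch0", "ch1"])["ch2"] == pytest.approx(1.0)

    def test_stated_arithmetic(self):
        s = self.series([100.0, 300.0, 400.0])
        assert log2_ratio_to_control(s, ["ch0", "ch1"])["ch2"] == pytest.approx(1.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValidationError):
            log2_ratio_to_control(self.series([0.0, 0.0, 10.0]), ["ch0", "ch1"])


class TestWeightedAggregation:
    def records(self, ratios, weights):
        return pd.DataFrame({"protein_id": "P1", "channel": "trt1",
                             "spectrum_id": [f"s{i}" for i in range(len(ratios))],
                             "log2_ratio": ratios, "weight": weights,
                             "mean_intensity": 1e5})

    def test_singleton(self):
        out = aggregate_weighted(self.records([1.7], [2.0]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.7)

    def test_uniform_weights_equal_plain_mean_exactly(self):
        ratios = [0.1, 0.30000000000000004, 0.7, -0.2]
        out = aggregate_weighted(self.records(ratios, [3.7] * 4))
        assert out["log2_ratio"].iloc[0] == np.mean(ratios)  # exact

    def test_weighted_mean_arithmetic(self):
        out = aggregate_weighted(self.records([1.0, 3.0], [3.0, 1.0]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.5)

    def test_variance_model_downweights_low_intensity(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            intensity = 10.0 ** rng.uniform(2, 6)
            noise_sd = 0.05 + 50.0 / math.sqrt(intensity)
            for rep in range(3):
                rows.append({"spectrum_id": f"s{i}_{rep}", "protein_id": f"P{i}",
                             "channel": "trt1",
                             "log2_ratio": rng.normal(0, noise_sd),
                             "mean_intensity": intensity, "weight": 1.0})
        records = estimate_inverse_variance_weights(pd.DataFrame(rows))
        low = records[records.mean_intensity < 1e3]["weight"].mean()
        high = records[records.mean_intensity > 1e5]["weight"].mean()
        assert high > low


class TestStandardize:
    def test_three_values(self):
        np.testing.assert_allclose(standardize_zscores([1.0, 2.0, 3.0]), [-1, 0, 1])

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        x = np.array([0.3, -1.2, 2.5, 0.9, -0.4])
        np.testing.assert_allclose(standardize_zscores(x * scale + shift),
                                   standardize_zscores(x), atol=1e-9)

    @given(st.integers(0, 500))
    def test_mean_zero_sd_one(self, seed):
        x = np.random.default_rng(seed).normal(3, 7, 40)
        z = standardize_zscores(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_dispersion_rejected(self):
        with pytest.raises(NumericalError):
            standardize_zscores([2.0, 2.0, 2.0])


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_proteins([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = ttest_proteins(a, b)
        t_ref, df = pooled_two_sample_t(a, b)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df), abs=1e-9)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_separation_limit(self):
        p_prev = 1.0
        for jitter in (1e-2, 1e-4, 1e-6):
            a = np.array([0.0, 0.0, 0.0]) + np.array([-1, 0, 1]) * jitter
            b = np.array([1.0, 1.0, 1.0]) + np.array([1, -1, 0]) * jitter
            _, p = ttest_proteins(a, b)
            assert p < p_prev
            p_prev = p
        assert ttest_proteins([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])[1] == 0.0

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            ttest_proteins([1.0], [1.0, 2.0])


class TestEnrichment:
    def test_exact_combinatorial_count(self):
        universe = [f"g{i}" for i in range(20)]
        collection = GeneSetCollection({"set": frozenset(universe[:5])})
        out = hypergeometric_enrichment(universe[:5], collection, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_empty_hits(self):
        universe = [f"g{i}" for i in range(20)]
        collection = GeneSetCollection({"set": frozenset(universe[:5])})
        out = hypergeometric_enrichment([], collection, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    @given(st.integers(0, 200))
    def test_matches_enumeration_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(8, 25))
        universe = [f"g{i}" for i in range(m)]
        set_size = int(rng.integers(1, m))
        n_hits = int(rng.integers(0, m))
        members = frozenset(rng.choice(universe, set_size, replace=False))
        hits = list(rng.choice(universe, n_hits, replace=False))
        out = hypergeometric_enrichment(hits, GeneSetCollection({"s": members}), universe)
        k = len(members & set(hits))
        expected = hypergeom_tail_enumeration(k, m, set_size, n_hits)
        assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_bh_q_at_least_p_and_order_invariant(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"s{j}": frozenset(universe[j:j + 6]) for j in range(6)}
        hits = universe[:5]
        out1 = hypergeometric_enrichment(hits, GeneSetCollection(sets), universe)
        reordered = dict(reversed(list(sets.items())))
        out2 = hypergeometric_enrichment(hits, GeneSetCollection(reordered), universe)
        assert (out1["q_value"] >= out1["p_value"] - 1e-15).all()
        pd.testing.assert_frame_equal(out1, out2)

    def test_hits_outside_universe_excluded(self):
        universe = [f"g{i}" for i in range(10)]
        collection = GeneSetCollection({"s": frozenset(universe[:3])})
        out = hypergeometric_enrichment(["g0", "not_measured"], collection, universe)
        assert out.attrs["n_hits_outside_universe"] == 1
        assert out.attrs["n_hits_tested"] == 1


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pathwayA\tdesc\tg1\tg2\tg3\npathwayB\tdesc\tg2\tg4\n")
    collection = read_gmt(path)
    assert collection.sets["pathwayA"] == frozenset({"g1", "g2", "g3"})
    assert len(collection) == 2
    bad = tmp_path / "bad.gmt"
    bad.write_text("only_name\n")
    with pytest.raises(ValidationError):
        read_gmt(bad)


def test_spectrum_ratio_table_and_controls():
    rows = []
    for spec_id, base in (("s1", 100.0), ("s2", 200.0)):
        for ch, scale in (("ctrl1", 1.0), ("ctrl2", 1.0), ("trt1", 2.0)):
            rows.append({"spectrum_id": spec_id, "protein_id": "P1",
                         "channel": ch, "intensity": base * scale})
    out = spectrum_ratio_table(pd.DataFrame(rows), ["ctrl1", "ctrl2"])
    trt = out[out.channel == "trt1"]
    np.testing.assert_allclose(trt["log2_ratio"], 1.0)
    ctrl = out[out.channel.str.startswith("ctrl")]
    np.testing.assert_allclose(ctrl["log2_ratio"], 0.0)
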