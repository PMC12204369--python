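import itertools

import numpy as np
import pandas as pd
import pytest

from chromodomain3d.morphometry_stats import (
    batch_t_summary,
    gini_index,
    length_volume_regression,
    nonparametric_battery,
    normality_check,
    one_sided_t,
    per_cell_gini,
    significance_code,
    volume_class_distribution,
)


class TestOneSidedT:
    def test_identical_groups_centered(self):
        res = one_sided_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], alternative="greater")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_large_shift_is_decisive(self):
        a = np.array([1.0, 2.0, 3.0])
        res = one_sided_t(a + 100.0, a, alternative="greater")
        assert res.p_value < 0.001

    def test_swapping_groups_flips_one_sided_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        p1 = one_sided_t(a, b, alternative="greater").p_value
        p2 = one_sided_t(b, a, alternative="greater").p_value
        assert p1 + p2 == pytest.approx(1.0)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sided_t([2.0, 2.0], [5.0, 5.0])


def feature_frame(batches, effect=0.0, seed=0, n=30):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(batches):
        for cond, mu in (("E2", effect), ("ED", 0.0)):
            for v in rng.normal(mu, 1.0, size=n):
                rows.append({"batch": f"b{b}", "cell": "c0", "condition": cond,
                             "volume": v})
    return pd.DataFrame(rows)


class TestBatchT:
    def test_upward_shift_gives_positive_t_everywhere(self):
        out = batch_t_summary(feature_frame(3, effect=2.0), "volume", ("E2", "ED"))
        assert len(out) == 3
        assert (out["t"] > 0).all()

    def test_downward_shift_gives_negative_t(self):
        out = batch_t_summary(feature_frame(3, effect=-2.0), "volume", ("E2", "ED"))
        assert (out["t"] < 0).all()

    def test_null_ts_are_centered(self):
        out = batch_t_summary(feature_frame(20, effect=0.0, seed=3), "volume",
                              ("E2", "ED"))
        assert abs(out["t"].mean()) < 0.8

    def test_batch_missing_condition_is_skipped(self):
        df = feature_frame(2, effect=1.0)
        df = df[~((df.batch == "b1") & (df.condition == "ED"))]
        out = batch_t_summary(df, "volume", ("E2", "ED"))
        assert list(out["batch"]) == ["b0"]


def frame_from_groups(**groups):
    rows = [
        {"condition": name, "value": float(v)}
        for name, values in groups.items()
        for v in values
    ]
    return pd.DataFrame(rows)


class TestNonparametricBattery:
    def test_identical_groups_stop_at_omnibus(self):
        df = frame_from_groups(a=range(10), b=range(10), c=range(10))
        out = nonparametric_battery(df, "value")
        assert out.omnibus.p_value > 0.5
        assert out.pairwise == []

    def test_separated_groups_all_pairwise_significant(self):
        df = frame_from_groups(a=range(1, 21), b=range(31, 51), c=range(61, 81))
        out = nonparametric_battery(df, "value")
        assert out.omnibus.p_value < 0.001
        assert len(out.pairwise) == 3
        for t in out.pairwise:
            assert t.corrected_p < 0.01
            assert t.corrected_p >= t.p_value
            assert t.corrected_p <= 1.0

    def test_two_conditions_give_single_pair(self):
        df = frame_from_groups(a=range(12), b=range(40, 52))
        out = nonparametric_battery(df, "value")
        assert len(out.pairwise) == 1
        assert out.pairwise[0].corrected_p == pytest.approx(out.pairwise[0].p_value)

    def test_tiny_groups_rejected(self):
        df = frame_from_groups(a=[1, 2], b=[3, 4, 5])
        with pytest.raises(ValueError):
            nonparametric_battery(df, "value")


class TestNormality:
    def test_normal_sample_passes_both(self):
        x = np.random.default_rng(7).normal(10, 2, size=500)
        sw, ks = normality_check(x)
        assert sw.p_value > 0.05 and ks.p_value > 0.05

    def test_lognormal_sample_fails_shapiro(self):
        x = np.exp(np.random.default_rng(7).normal(0, 1, size=500))
        sw, _ = normality_check(x)
        assert sw.p_value < 0.001

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check(np.full(10, 3.0))


class TestGini:
    def test_equal_values_give_zero(self):
        assert gini_index(np.full(50, 120.0)) == 0.0

    def test_zero_one_pair_gives_half(self):
        assert gini_index([0.0, 1.0]) == pytest.approx(0.5)

    def test_single_value_gives_zero(self):
        assert gini_index([7.0]) == 0.0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.random(rng.integers(2, 200)) * 100
            n, mu = len(x), x.mean()
            brute = sum(abs(a - b) for a, b in itertools.product(x, x)) / (
                2 * n**2 * mu
            )
            assert gini_index(x) == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_positive_rescaling(self):
        x = np.array([1.0, 4.0, 9.0, 2.0])
        assert gini_index(17.0 * x) == pytest.approx(gini_index(x))

    def test_concentration_increases_gini(self):
        spread = [25.0, 25.0, 25.0, 25.0]
        concentrated = [70.0, 20.0, 7.0, 3.0]
        assert gini_index(concentrated) > gini_index(spread)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_index([0.0, 0.0])

    def test_per_cell_grouping(self):
        df = pd.DataFrame({
            "batch": ["b0"] * 4, "cell": ["c0", "c0", "c1", "c1"],
            "condition": ["E2"] * 4, "volume_vox": [10.0, 10.0, 1.0, 9.0],
        })
        out = per_cell_gini(df, ["volume_vox"])
        by_cell = dict(zip(out["cell"], out["gini"]))
        assert by_cell["c0"] == 0.0
        assert by_cell["c1"] == pytest.approx(0.4)


class TestVolumeClasses:
    def test_auto_quartile_edges_give_quarter_fractions(self):
        df = pd.DataFrame({"condition": ["a"] * 100,
                           "volume_vox": np.arange(1.0, 101.0)})
        (dist,) = volume_class_distribution(df)
        assert dist.fractions == pytest.approx((0.25, 0.25, 0.25, 0.25), abs=0.01)
        assert sum(dist.fractions) == pytest.approx(1.0)

    def test_fixed_edges_match_manual_binning(self):
        vols = [5.0, 50.0, 500.0, 5000.0, 7.0, 70.0]
        df = pd.DataFrame({"condition": ["a"] * 6, "volume_vox": vols})
        (dist,) = volume_class_distribution(df, edges=(10.0, 100.0, 1000.0))
        assert dist.fractions == pytest.approx((2 / 6, 2 / 6, 1 / 6, 1 / 6))

    def test_condition_without_volumes_rejected(self):
        df = pd.DataFrame({"condition": ["a"], "volume_vox": [1.0]})
        with pytest.raises(ValueError):
            volume_class_distribution(df, conditions=["a", "ghost"],
                                      edges=(1.0, 2.0, 3.0))

    def test_too_few_distinct_volumes_for_auto_edges(self):
        df = pd.DataFrame({"condition": ["a"] * 8, "volume_vox": [5.0] * 8})
        with pytest.raises(ValueError, match="distinct"):
            volume_class_distribution(df)


class TestRegression:
    def test_exact_line_recovered(self):
        df = pd.DataFrame({
            "condition": ["a"] * 5,
            "length_um": [1.0, 2.0, 3.0, 4.0, 5.0],
            "volume_um3": [4.0, 7.0, 10.0, 13.0, 16.0],  # 3x + 1
        })
        out = length_volume_regression(df, "a")
        assert out["slope"] == pytest.approx(3.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_permuted_pairing_has_no_relationship(self):
        rng = np.random.default_rng(2)
        lengths = np.linspace(1, 10, 200)
        volumes = 3 * lengths + 1
        df = pd.DataFrame({"condition": ["a"] * 200, "length_um": lengths,
                           "volume_um3": rng.permutation(volumes)})
        assert length_volume_regression(df, "a")["r_squared"] < 0.05

    def test_zero_length_variance_rejected(self):
        df = pd.DataFrame({"condition": ["a"] * 4, "length_um": [2.0] * 4,
                           "volume_um3": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="length variance"):
            length_volume_regression(df, "a")


def test_significance_codes():
    assert significance_code(0.2) == "ns"
    assert significance_code(0.04) == "*"
    assert significance_code(0.009) == "**"
    assert significance_code(0.0009) == "***"
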