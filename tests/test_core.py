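import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alteredpqr import (call_outliers, compute_log_ratios, make_pairs,
                        modified_z, normality_diagnostic, reference_stats)

# well-scaled values: keeps the raw MAD either exactly 0 or >= 5e-4, so the
# invariance checks are not dominated by float cancellation
finite = st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 3))


def _ratio_frame(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(["A::B"], name="pair"),
                        columns=samples)


class TestModifiedZ:
    @pytest.mark.parametrize("x, med, mad, expected", [
        (1.0, 1.0, 0.05, 0.0),                  # at the median
        (1.05, 1.0, 0.05, 0.6745),              # one MAD above -> the constant
        (1.5, 1.0, 0.05, 6.745),                # 0.6745 * 0.5 / 0.05
        (0.5, 1.0, 0.05, -6.745),               # sign preserved
    ])
    def test_values(self, x, med, mad, expected):
        assert modified_z(x, med, mad) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_mad_rejected(self):
        with pytest.raises(ValueError):
            modified_z(1.0, 0.0, 0.0)


class TestReferenceStats:
    def test_hand_computed_median_and_mad(self):
        ratios = _ratio_frame([[1.0, 1.1, 0.9, 1.05, 0.95]])
        st_ = reference_stats(ratios, ratios.columns, min_ref_obs=5)
        assert st_.loc["A::B", "ref_median"] == pytest.approx(1.0)
        assert st_.loc["A::B", "ref_mad"] == pytest.approx(0.05)
        assert bool(st_.loc["A::B", "testable"])

    def test_constant_reference_is_untestable(self):
        ratios = _ratio_frame([[2.0] * 6])
        st_ = reference_stats(ratios, ratios.columns, min_ref_obs=5)
        assert st_.loc["A::B", "ref_mad"] == 0.0
        assert not st_.loc["A::B", "testable"]

    def test_too_few_observations_untestable(self):
        ratios = _ratio_frame([[1.0, 1.2, np.nan, np.nan, np.nan]])
        st_ = reference_stats(ratios, ratios.columns, min_ref_obs=5)
        assert st_.loc["A::B", "n_ref_obs"] == 2
        assert not st_.loc["A::B", "testable"]


class TestLogRatios:
    def test_orientation_and_missing(self, tiny_matrix, tiny_pairs):
        ratios = compute_log_ratios(tiny_matrix, tiny_pairs)
        # A - B (alphabetical first minus second)
        assert ratios.loc["A::B", "R1"] == pytest.approx(2.0)
        # missing C in T2 propagates to the pair
        assert np.isnan(ratios.loc["A::C", "T2"])

    def test_identical_profiles_give_zero_ratio(self):
        m = pd.DataFrame({"S1": [4.0, 4.0], "S2": [6.5, 6.5]},
                         index=["A", "B"])
        pairs = make_pairs([("A", "B")], m)
        ratios = compute_log_ratios(m, pairs)
        assert (ratios.loc["A::B"] == 0).all()


class TestOutlierCalls:
    def _calls(self, ref, test, z_threshold=3.5):
        ratios = _ratio_frame([list(ref) + list(test)])
        ref_cols = list(ratios.columns[:len(ref)])
        test_cols = list(ratios.columns[len(ref):])
        stats = reference_stats(ratios, ref_cols, min_ref_obs=3)
        return call_outliers(ratios, stats, test_cols, z_threshold)

    def test_score_is_sum_of_flagged_magnitudes(self):
        # ref median 1.0, MAD 0.05 -> Mi of (1.5, 0.7(.35 short of flag), 1.2)
        ref = [1.0, 1.1, 0.9, 1.05, 0.95]
        calls = self._calls(ref, [1.5, 1.2, 1.0 - 4.0 * 0.05 / 0.6745])
        mi = calls.mi.loc["A::B"].to_numpy()
        assert mi[0] == pytest.approx(6.745)
        assert mi[2] == pytest.approx(-4.0)
        assert calls.flags.loc["A::B"].tolist() == [True, False, True]
        assert calls.scores["A::B"] == pytest.approx(6.745 + 4.0)

    def test_threshold_is_strict(self):
        ref = [1.0, 1.1, 0.9, 1.05, 0.95]
        x_at_3_5 = 1.0 + 3.5 * 0.05 / 0.6745  # Mi exactly 3.5
        calls = self._calls(ref, [x_at_3_5])
        assert calls.mi.loc["A::B"].iloc[0] == pytest.approx(3.5)
        assert not calls.flags.loc["A::B"].iloc[0]
        assert calls.scores["A::B"] == 0.0

    def test_no_outliers_gives_zero_score(self):
        calls = self._calls([1.0, 1.1, 0.9, 1.05, 0.95], [1.0, 1.02])
        assert calls.scores["A::B"] == 0.0
        assert not calls.flags.loc["A::B"].any()


class TestInvariances:
    @given(st.lists(finite, min_size=8, max_size=8),
           st.floats(-10, 10, allow_nan=False),
           st.floats(0.1, 10, allow_nan=False))
    def test_shift_and_scale_leave_mi_unchanged(self, vals, c, k):
        ratios = _ratio_frame([vals])
        stats = reference_stats(ratios, ratios.columns[:5], min_ref_obs=3)
        if not stats["testable"].iloc[0]:
            return
        base = call_outliers(ratios, stats, ratios.columns[5:]).mi
        for transformed in (ratios + c, ratios * k):
            st2 = reference_stats(transformed, ratios.columns[:5],
                                  min_ref_obs=3)
            if not st2["testable"].iloc[0]:
                continue  # float absorption collapsed the MAD to 0
            mi2 = call_outliers(transformed, st2, ratios.columns[5:]).mi
            np.testing.assert_allclose(mi2.to_numpy(), base.to_numpy(),
                                       rtol=1e-9, atol=1e-9)

    @given(st.lists(finite, min_size=8, max_size=8))
    def test_orientation_swap_negates_mi(self, vals):
        ratios = _ratio_frame([vals])
        stats = reference_stats(ratios, ratios.columns[:5], min_ref_obs=3)
        if not stats["testable"].iloc[0]:
            return
        calls = call_outliers(ratios, stats, ratios.columns[5:])
        swapped = -ratios
        st2 = reference_stats(swapped, ratios.columns[:5], min_ref_obs=3)
        calls2 = call_outliers(swapped, st2, ratios.columns[5:])
        np.testing.assert_allclose(calls2.mi.to_numpy(),
                                   -calls.mi.to_numpy(), atol=1e-9)
        assert calls2.scores["A::B"] == pytest.approx(calls.scores["A::B"])


def test_pipeline_matches_brute_force_oracle():
    """Mi from the vectorized path equals explicit median/MAD loops."""
    rng = np.random.default_rng(5)
    n_pairs, n_ref, n_test = 50, 12, 8
    vals = rng.normal(0, 1, size=(n_pairs, n_ref + n_test))
    cols = [f"R{i}" for i in range(n_ref)] + [f"T{i}" for i in range(n_test)]
    ratios = pd.DataFrame(vals, index=[f"p{i}::q{i}" for i in range(n_pairs)],
                          columns=cols)
    stats = reference_stats(ratios, cols[:n_ref], min_ref_obs=5)
    calls = call_outliers(ratios, stats, cols[n_ref:])
    for i, pair in enumerate(ratios.index):
        ref = sorted(vals[i, :n_ref])
        med = (ref[n_ref // 2 - 1] + ref[n_ref // 2]) / 2
        devs = sorted(abs(v - med) for v in vals[i, :n_ref])
        mad = (devs[n_ref // 2 - 1] + devs[n_ref // 2]) / 2
        for j, s in enumerate(cols[n_ref:]):
            expected = 0.6745 * (vals[i, n_ref + j] - med) / mad
            assert abs(calls.mi.loc[pair, s] - expected) < 1e-12


class TestNormalityDiagnostic:
    def test_normal_references_mostly_pass(self):
        rng = np.random.default_rng(3)
        ratios = pd.DataFrame(rng.normal(0, 1, size=(100, 10)),
                              index=[f"p{i}::q{i}" for i in range(100)],
                              columns=[f"R{i}" for i in range(10)])
        diag = normality_diagnostic(ratios, ratios.columns)
        assert diag.fraction_normal >= 0.85  # test size ~ alpha = 0.05

    def test_bimodal_pair_rejected_and_constant_excluded(self):
        rng = np.random.default_rng(4)
        bimodal = np.concatenate([rng.normal(0, 0.05, 10),
                                  rng.normal(5, 0.05, 10)])
        data = np.vstack([bimodal, np.zeros(20)])
        ratios = pd.DataFrame(data, index=["a::b", "c::d"],
                              columns=[f"R{i}" for i in range(20)])
        diag = normality_diagnostic(ratios, ratios.columns)
        assert diag.p_values["a::b"] < 0.05
        assert "c::d" not in diag.p_values.index
        assert diag.n_constant == 1
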