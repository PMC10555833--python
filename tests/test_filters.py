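import numpy as np
import pandas as pd
import pytest

from alteredpqr import make_pairs
from alteredpqr.core import reference_stats
from alteredpqr.filters import (STATUS_ANNOTATION, STATUS_KEPT, STATUS_MERGED,
                                STATUS_VAR_PAIR, STATUS_VAR_PROTEIN,
                                annotation_filter, contribution_test,
                                protein_outlier_profiles,
                                reference_variability_filter,
                                select_representative_pairs,
                                variable_proteins)
from alteredpqr.io import ExclusionList


class TestVariableProteins:
    def test_trimodal_reference_protein_flagged(self):
        # median 5.075, raw MAD 0.15, band 5.075 +/- 1.4826*2*0.15 = +/-0.445
        # -> the three 9.x samples fall outside -> flagged
        vals = [5.0, 5.1, 4.9, 5.05, 4.95, 5.2, 4.8, 9.0, 9.1, 9.2]
        m = pd.DataFrame([vals], index=["H"],
                         columns=[f"R{i}" for i in range(10)])
        assert variable_proteins(m, m.columns) == {"H"}

    def test_degenerate_mad_uses_collapsed_band(self):
        # median 0, MAD 0: any value off the median counts as outside
        vals = [0.0] * 7 + [10.0, 10.0, 10.0]
        m = pd.DataFrame([vals], index=["H"],
                         columns=[f"R{i}" for i in range(10)])
        assert variable_proteins(m, m.columns) == {"H"}

    def test_well_behaved_protein_kept(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(10, 0.2, size=(5, 10)),
                         index=[f"P{i}" for i in range(5)],
                         columns=[f"R{i}" for i in range(10)])
        assert variable_proteins(m, m.columns) == set()


class TestPairVariability:
    def test_pair_with_three_deviant_reference_samples_removed(self):
        # tight central cluster -> tiny MAD -> the three 10s blow past 3.5
        ref = [0.0, 0.01, -0.01, 0.02, -0.02, 0.015, -0.015, 10, 10, 10]
        cols = [f"R{i}" for i in range(10)]
        ratios = pd.DataFrame([ref], index=["A::B"], columns=cols)
        stats = reference_stats(ratios, cols)
        matrix = pd.DataFrame(np.zeros((2, 10)) + [[5.0], [7.0]],
                              index=["A", "B"], columns=cols)
        matrix += np.random.default_rng(1).normal(0, 0.05, matrix.shape)
        pairs = make_pairs([("A", "B")], matrix)
        status = reference_variability_filter(ratios, stats, pairs, matrix,
                                              cols)
        assert status["A::B"] == STATUS_VAR_PAIR


class TestAnnotationFilter:
    def _pairs(self):
        return make_pairs([("ACTB", "X"), ("Y", "Z")])

    def test_excluded_protein_removes_pair_with_reason(self):
        excl = ExclusionList(frozenset({"ACTB"}), "GO:0005200")
        report = annotation_filter(self._pairs(), [excl])
        assert report.loc["ACTB::X", "status"] == STATUS_ANNOTATION
        assert report.loc["ACTB::X", "reason"] == "GO:0005200"
        assert report.loc["Y::Z", "status"] == STATUS_KEPT

    def test_empty_exclusions_keep_everything(self):
        report = annotation_filter(self._pairs(), [])
        assert (report["status"] == STATUS_KEPT).all()

    def test_protein_on_two_lists_logs_both_reasons(self):
        lists = [ExclusionList(frozenset({"ACTB"}), "GO:0005200"),
                 ExclusionList(frozenset({"ACTB"}), "GO:0003735")]
        report = annotation_filter(self._pairs(), lists)
        assert report.loc["ACTB::X", "reason"] == "GO:0005200;GO:0003735"


def _profiles(mi_by_protein, samples):
    mi = pd.DataFrame(mi_by_protein, index=samples).T
    from alteredpqr.filters import ProteinOutlierProfiles
    return ProteinOutlierProfiles(
        mi=mi, ref_median=pd.Series(0.0, index=mi.index),
        ref_mad=pd.Series(1.0, index=mi.index), n_degenerate=0)


class TestContribution:
    samples = ["T1", "T2", "T3", "T4"]

    def test_half_of_flagged_samples_suffices(self):
        prof = _profiles({"A": [3.0, 2.5, 0.1, 0.2],
                          "B": [0.0, 0.1, 0.0, 0.1]}, self.samples)
        out = contribution_test(self.samples, "A", "B", prof)
        assert out == {"A"}  # 2 of 4 >= half

    def test_one_of_three_fails_two_of_three_passes(self):
        prof = _profiles({"A": [3.0, 0.0, 0.0, np.nan],
                          "B": [3.0, -2.5, 0.0, np.nan]}, self.samples)
        out = contribution_test(["T1", "T2", "T3"], "A", "B", prof)
        assert out == {"B"}

    def test_opposite_mild_shifts_both_contribute(self):
        prof = _profiles({"A": [2.5, 2.6, 2.4, 2.5],
                          "B": [-2.5, -2.4, -2.6, -2.5]}, self.samples)
        assert contribution_test(self.samples, "A", "B", prof) == {"A", "B"}

    def test_no_flagged_samples_no_contributors(self):
        prof = _profiles({"A": [9.0] * 4, "B": [9.0] * 4}, self.samples)
        assert contribution_test([], "A", "B", prof) == set()


class TestRepresentativeSelection:
    def _table(self, scores, adj=None):
        idx = list(scores)
        return pd.DataFrame({
            "score": [scores[p] for p in idx],
            "adj_p_value": [adj[p] if adj else 0.01 for p in idx]},
            index=idx)

    def test_hub_protein_keeps_highest_scoring_pair(self):
        scores = {"A::H": 12.0, "B::H": 30.0, "C::H": 9.0}
        contrib = {p: {"H"} for p in scores}
        report = select_representative_pairs(self._table(scores), contrib)
        assert report.loc["B::H", "status"] == STATUS_KEPT
        assert report.loc["A::H", "status"] == STATUS_MERGED
        assert report.loc["A::H", "representative"] == "B::H"
        assert report.loc["C::H", "representative"] == "B::H"

    def test_tie_broken_by_adj_p_then_pair_id(self):
        scores = {"A::H": 10.0, "B::H": 10.0, "C::H": 10.0}
        adj = {"A::H": 0.05, "B::H": 0.01, "C::H": 0.01}
        report = select_representative_pairs(self._table(scores, adj),
                                             {p: {"H"} for p in scores})
        assert report.loc["B::H", "status"] == STATUS_KEPT  # smaller adj p,
        assert report.loc["C::H", "status"] == STATUS_MERGED  # then lexicographic

    def test_disjoint_pairs_kept_unchanged(self):
        scores = {"A::B": 10.0, "C::D": 8.0}
        report = select_representative_pairs(
            self._table(scores), {"A::B": {"A"}, "C::D": {"D"}})
        assert (report["status"] == STATUS_KEPT).all()

    def test_no_contributor_pairs_retained_and_flagged(self):
        scores = {"A::B": 10.0}
        report = select_representative_pairs(self._table(scores),
                                             {"A::B": set()})
        assert report.loc["A::B", "status"] == STATUS_KEPT
        assert bool(report.loc["A::B", "no_contributor"])


def test_protein_profiles_degenerate_reference_counted():
    cols = [f"R{i}" for i in range(6)] + ["T1"]
    m = pd.DataFrame([[1.0] * 6 + [5.0],
                      [1.0, 1.2, 0.8, 1.1, 0.9, 1.05, 5.0]],
                     index=["flat", "ok"], columns=cols)
    prof = protein_outlier_profiles(m, cols[:6], ["T1"], min_ref_obs=5)
    assert prof.n_degenerate == 1
    assert np.isnan(prof.mi.loc["flat", "T1"])
    assert prof.mi.loc["ok", "T1"] > 2


def test_relabeling_yields_isomorphic_filter_report(null_dataset):
    matrix, design, pairs, _, _ = null_dataset
    ref = [s for s in matrix.columns if s.startswith("R")]
    ratios_idx = pairs[pairs["measured"]]
    from alteredpqr.core import compute_log_ratios
    ratios = compute_log_ratios(matrix, ratios_idx)
    stats = reference_stats(ratios, ref)
    testable = stats.index[stats["testable"]]
    status = reference_variability_filter(
        ratios, stats, ratios_idx.loc[testable], matrix, ref)

    # order-preserving rename P -> Q keeps pair orientation identical
    rename = {p: "Q" + p[1:] for p in matrix.index}
    m2 = matrix.rename(index=rename)
    pairs2 = make_pairs([(rename[a], rename[b]) for a, b in
                         zip(ratios_idx["protein_a"], ratios_idx["protein_b"])],
                        matrix=m2)
    ratios2 = compute_log_ratios(m2, pairs2)
    stats2 = reference_stats(ratios2, ref)
    testable2 = stats2.index[stats2["testable"]]
    status2 = reference_variability_filter(
        ratios2, stats2, pairs2.loc[testable2], m2, ref)
    mapped = {f"Q{a[1:]}::Q{b[1:]}": s for (a, b), s in
              zip(zip(ratios_idx.loc[testable, "protein_a"],
                      ratios_idx.loc[testable, "protein_b"]), status)}
    assert dict(status2) == mapped
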