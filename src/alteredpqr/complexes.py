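"""Complex-level analyses.

Two views of a complex catalog: (1) over-representation of each complex
among the proteins flagged by the pair-level screen (two-sided Fisher exact
test over the analyzed background, BH-adjusted); (2) whole-complex up/down
regulation — the complex is summarized per sample by the median log
quantity of its reliably measured subunits and that trace is screened with
the same modified-z machinery as pair ratios, keeping complexes that are
outliers in at least 10% of evaluable test samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import DEFAULT_Z_THRESHOLD, call_outliers, reference_stats
from .io import catalog_members, design_groups, validate_quant_matrix
from .significance import bh_adjust


def complex_overrepresentation(significant_proteins, background_proteins,
                               catalog: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact test per complex.

    The 2×2 table counts membership in the complex against membership in
    the significant set, over ``background_proteins`` (which must contain
    the significant set). Complexes with no measured member are skipped.
    """
    sig = set(significant_proteins)
    bg = set(background_proteins)
    if not sig <= bg:
        raise ValueError("background must contain all significant proteins")
    rows = []
    for cid, (name, members) in catalog_members(catalog).items():
        mem = set(members) & bg
        if not mem:
            continue
        a = len(mem & sig)
        b = len(mem - sig)
        c = len(sig - mem)
        d = len(bg) - a - b - c
        p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        rows.append((cid, name, len(mem), a, p))
    out = pd.DataFrame(rows, columns=["complex_id", "name", "n_measured",
                                      "n_significant", "p_value"])
    if len(out):
        out["adj_p_value"] = bh_adjust(out["p_value"])
        out = out.sort_values(["p_value", "complex_id"]).set_index("complex_id")
    return out


def complex_median_profile(matrix: pd.DataFrame, catalog: pd.DataFrame,
                           majority_fraction: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Median-subunit expression trace per complex.

    Subunits are kept only when measured in strictly more than
    ``majority_fraction`` of all samples; the per-sample complex value is
    the median over kept subunits and exists only where every kept subunit
    is measured. Complexes with fewer than 2 kept subunits are dropped.

    Returns (trace matrix complexes × samples, {complex_id: kept subunits}).
    """
    n_samples = matrix.shape[1]
    traces = {}
    kept = {}
    for cid, (name, members) in catalog_members(catalog).items():
        present = [m for m in members if m in matrix.index]
        sub = matrix.loc[present]
        counts = sub.notna().sum(axis=1)
        keep = list(sub.index[counts > majority_fraction * n_samples])
        if len(keep) < 2:
            continue
        block = matrix.loc[keep]
        trace = block.median(axis=0)
        trace[block.isna().any(axis=0)] = np.nan
        traces[cid] = trace
        kept[cid] = keep
    trace_df = pd.DataFrame(traces).T
    trace_df.index.name = "complex_id"
    if trace_df.empty:
        trace_df = pd.DataFrame(columns=matrix.columns)
    return trace_df, kept


def complex_outlier_scan(trace: pd.DataFrame, design: pd.DataFrame,
                         z_threshold: float = DEFAULT_Z_THRESHOLD,
                         min_fraction: float = 0.10,
                         min_ref_obs: int = 5) -> pd.DataFrame:
    """Screen complex median traces for repeated test-sample outliers.

    Applies the modified-z machinery to each complex trace; a complex is
    retained when it is flagged in at least ``min_fraction`` of evaluable
    test samples (samples where its value exists). Both the evaluable-based
    and the all-test-samples fraction are reported. Direction is the sign
    of the mean flagged Mi.
    """
    test_samples = [s for s in trace.columns
                    if s in design.index and design.loc[s, "group"] == "test"]
    ref_samples = [s for s in trace.columns
                   if s in design.index and design.loc[s, "group"] == "reference"]
    stats = reference_stats(trace, ref_samples, min_ref_obs=min_ref_obs)
    calls = call_outliers(trace, stats, test_samples, z_threshold=z_threshold)
    rows = []
    for cid in trace.index:
        if not stats.loc[cid, "testable"]:
            rows.append((cid, 0, 0, np.nan, np.nan, "", "untestable"))
            continue
        mi = calls.mi.loc[cid]
        flags = calls.flags.loc[cid]
        evaluable = int(mi.notna().sum())
        n_flag = int(flags.sum())
        frac = n_flag / evaluable if evaluable else np.nan
        frac_all = n_flag / len(test_samples) if test_samples else np.nan
        direction = ""
        if n_flag:
            direction = "up" if float(mi[flags].mean()) > 0 else "down"
        retained = evaluable > 0 and frac >= min_fraction and n_flag > 0
        rows.append((cid, n_flag, evaluable, frac, frac_all, direction,
                     "retained" if retained else "dropped"))
    return pd.DataFrame(rows, columns=[
        "complex_id", "n_flagged", "n_evaluable_test", "flagged_fraction",
        "flagged_fraction_all_test", "direction", "status"]
    ).set_index("complex_id")


class ComplexProfiler(BaseEstimator):
    """Whole-complex regulation screen (median-subunit trace + outlier scan).

    Attributes
    ----------
    trace_ : pandas.DataFrame
        Complex × sample median-subunit expression values.
    kept_subunits_ : dict
        complex_id -> subunits entering the median.
    results_ : pandas.DataFrame
        Outlier-scan table with flagged fractions, direction and status.
    """

    def __init__(self, majority_fraction: float = 0.5,
                 z_threshold: float = DEFAULT_Z_THRESHOLD,
                 min_fraction: float = 0.10, min_ref_obs: int = 5):
        self.majority_fraction = majority_fraction
        self.z_threshold = z_threshold
        self.min_fraction = min_fraction
        self.min_ref_obs = min_ref_obs

    def fit(self, X: pd.DataFrame, design: pd.DataFrame,
            catalog: pd.DataFrame):
        X = validate_quant_matrix(X)
        X = X.loc[:, [s for s in X.columns if s in design.index]]
        self.trace_, self.kept_subunits_ = complex_median_profile(
            X, catalog, self.majority_fraction)
        self.results_ = complex_outlier_scan(
            self.trace_, design, z_threshold=self.z_threshold,
            min_fraction=self.min_fraction, min_ref_obs=self.min_ref_obs)
        names = {cid: nm for cid, (nm, _) in catalog_members(catalog).items()}
        self.results_.insert(0, "name",
                             [names.get(c, "") for c in self.results_.index])
        self.results_.insert(1, "kept_subunits",
                             [";".join(self.kept_subunits_.get(c, []))
                              for c in self.results_.index])
        return self

    def retained(self) -> pd.DataFrame:
        check_is_fitted(self, "results_")
        return self.results_[self.results_["status"] == "retained"]
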