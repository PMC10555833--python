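"""Differential co-expression (correlation gain/loss) between sample groups.

For complex co-members, a strong gain of expression correlation in one
group relative to another indicates assembly of the complex in that group
(and symmetrically, loss indicates disassembly). A pair is classified
``gain_in_B`` when it is significantly correlated in group B
(Pearson r > 0.6 and BH-adjusted p <= 0.05), not significantly correlated
in group A, and the shift is large (|r_B - r_A| > 0.6); ``gain_in_A`` is
the mirror image. Correlation p-values use the exact t transform
t = r·sqrt(n-2)/sqrt(1-r²) with n-2 degrees of freedom (two-sided).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import compute_log_ratios  # noqa: F401  (shared conventions)
from .io import design_groups, validate_quant_matrix
from .significance import bh_adjust

GAIN_IN_A = "gain_in_A"
GAIN_IN_B = "gain_in_B"
NO_SHIFT = "no_shift"
UNTESTABLE = "untestable"


def group_correlation(matrix: pd.DataFrame, pairs: pd.DataFrame, samples,
                      min_obs: int = 8):
    """Pairwise-complete Pearson r per pair over the given samples.

    Returns (r, n) as float/int arrays aligned to ``pairs``; r is NaN where
    fewer than ``min_obs`` paired observations exist or a protein is
    constant over them.
    """
    a = matrix.reindex(pairs["protein_a"]).loc[:, list(samples)].to_numpy(float)
    b = matrix.reindex(pairs["protein_b"]).loc[:, list(samples)].to_numpy(float)
    m = ~np.isnan(a) & ~np.isnan(b)
    n = m.sum(axis=1)
    ax = np.where(m, a, 0.0)
    bx = np.where(m, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa, sb = ax.sum(1), bx.sum(1)
        saa, sbb, sab = (ax * ax).sum(1), (bx * bx).sum(1), (ax * bx).sum(1)
        cov = sab - sa * sb / np.maximum(n, 1)
        va = saa - sa * sa / np.maximum(n, 1)
        vb = sbb - sb * sb / np.maximum(n, 1)
        r = cov / np.sqrt(va * vb)
    r = np.clip(r, -1.0, 1.0)
    r[(n < min_obs) | ~np.isfinite(r)] = np.nan
    return r, n


def correlation_pvalue(r, n):
    """Two-sided p-value of a Pearson correlation via the t transform.

    ``p = 2·P(T_{n-2} >= |t|)`` with ``t = r·sqrt(n-2)/sqrt(1-r²)``;
    |r| = 1 returns 0. Vectorized; NaN r propagates.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    scalar = r.ndim == 0
    r, n = np.atleast_1d(r), np.atleast_1d(np.broadcast_to(n, r.shape))
    if np.any(n[~np.isnan(r)] < 3):
        raise ValueError("correlation p-value needs n >= 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(t, n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    return float(p[0]) if scalar else p


def classify_shift(r_a, adj_p_a, r_b, adj_p_b, r_threshold: float = 0.6,
                   p_threshold: float = 0.05,
                   delta_threshold: float = 0.6) -> str:
    """Classification of one pair given group-wise r and adjusted p."""
    if any(np.isnan(v) for v in (r_a, r_b)):
        return UNTESTABLE
    sig_a = (r_a > r_threshold) and (adj_p_a <= p_threshold)
    sig_b = (r_b > r_threshold) and (adj_p_b <= p_threshold)
    big = abs(r_b - r_a) > delta_threshold
    if sig_b and not sig_a and big:
        return GAIN_IN_B
    if sig_a and not sig_b and big:
        return GAIN_IN_A
    return NO_SHIFT


class CorShift(BaseEstimator):
    """Screen complex co-member pairs for correlation gain/loss between two
    sample groups.

    Parameters
    ----------
    group_a, group_b : str
        Labels of the two groups in the design column named by ``by``
        (default: the ``group`` column's ``reference``/``test``).
    by : str
        Design column holding the group labels (``group`` or ``subtype``).
    r_threshold, p_threshold, delta_threshold : float
        Significant-correlation and shift-size cutoffs.
    min_obs : int
        Minimum paired non-missing observations per group; below it a pair
        is untestable (correlation p-values are fragile at small n).

    Attributes
    ----------
    records_ : pandas.DataFrame
        One row per measured pair: r/n/p/adjusted p per group, ``delta_r``
        (r_B − r_A) and the classification. BH adjustment is performed
        within each group across all testable pairs. Sorted with classified
        gains first, by the gaining group's p-value.
    """

    def __init__(self, group_a: str = "reference", group_b: str = "test",
                 by: str = "group", r_threshold: float = 0.6,
                 p_threshold: float = 0.05, delta_threshold: float = 0.6,
                 min_obs: int = 8):
        self.group_a = group_a
        self.group_b = group_b
        self.by = by
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold
        self.delta_threshold = delta_threshold
        self.min_obs = min_obs

    def fit(self, X: pd.DataFrame, design: pd.DataFrame, pairs: pd.DataFrame,
            exclusions=()):
        """Compute group-wise correlations and classify every measured pair."""
        X = validate_quant_matrix(X)
        if self.by not in design.columns:
            raise ValueError(f"design has no column {self.by!r}")
        labels = design[self.by]
        samples_a = [s for s in X.columns
                     if s in set(labels.index[labels == self.group_a])]
        samples_b = [s for s in X.columns
                     if s in set(labels.index[labels == self.group_b])]
        for name, smp in ((self.group_a, samples_a), (self.group_b, samples_b)):
            if len(smp) < self.min_obs:
                raise ValueError(
                    f"group {name!r} has {len(smp)} samples; need >= "
                    f"{self.min_obs}")
        self.samples_a_, self.samples_b_ = samples_a, samples_b

        work = pairs[pairs["protein_a"].isin(X.index)
                     & pairs["protein_b"].isin(X.index)].copy()
        for excl in exclusions:
            ids = set(excl.protein_ids)
            work = work[~(work["protein_a"].isin(ids)
                          | work["protein_b"].isin(ids))]
        r_a, n_a = group_correlation(X, work, samples_a, self.min_obs)
        r_b, n_b = group_correlation(X, work, samples_b, self.min_obs)
        p_a = correlation_pvalue(r_a, n_a)
        p_b = correlation_pvalue(r_b, n_b)
        rec = pd.DataFrame({
            "protein_a": work["protein_a"], "protein_b": work["protein_b"],
            "r_a": r_a, "r_b": r_b, "n_a": n_a, "n_b": n_b,
            "p_a": p_a, "p_b": p_b}, index=work.index)
        testable = rec["r_a"].notna() & rec["r_b"].notna()
        rec["adj_p_a"] = np.nan
        rec["adj_p_b"] = np.nan
        rec.loc[testable, "adj_p_a"] = bh_adjust(rec.loc[testable, "p_a"])
        rec.loc[testable, "adj_p_b"] = bh_adjust(rec.loc[testable, "p_b"])
        rec["delta_r"] = rec["r_b"] - rec["r_a"]
        rec["classification"] = [
            classify_shift(row.r_a, row.adj_p_a, row.r_b, row.adj_p_b,
                           self.r_threshold, self.p_threshold,
                           self.delta_threshold) if ok else UNTESTABLE
            for ok, row in zip(testable, rec.itertuples())]
        gaining_p = np.where(rec["classification"] == GAIN_IN_A,
                             rec["p_a"],
                             np.where(rec["classification"] == GAIN_IN_B,
                                      rec["p_b"],
                                      np.fmin(rec["p_a"], rec["p_b"])))
        is_gain = rec["classification"].isin([GAIN_IN_A, GAIN_IN_B])
        rec = rec.assign(_gp=gaining_p, _g=~is_gain).sort_values(
            ["_g", "_gp", "protein_a", "protein_b"]).drop(columns=["_g", "_gp"])
        self.records_ = rec
        self.n_gain_a_ = int((rec["classification"] == GAIN_IN_A).sum())
        self.n_gain_b_ = int((rec["classification"] == GAIN_IN_B).sum())
        return self

    def gains(self) -> pd.DataFrame:
        check_is_fitted(self, "records_")
        return self.records_[
            self.records_["classification"].isin([GAIN_IN_A, GAIN_IN_B])]


def corshift_table(matrix: pd.DataFrame, design: pd.DataFrame,
                   pairs: pd.DataFrame, exclusions=(),
                   **params) -> pd.DataFrame:
    """One-call wrapper: fit :class:`CorShift` and return its records."""
    return CorShift(**params).fit(matrix, design, pairs,
                                  exclusions=exclusions).records_
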