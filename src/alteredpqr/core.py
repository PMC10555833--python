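"""Robust pair-ratio statistics.

The unit of analysis is the protein quantitative relationship (PQR): the
log-ratio of two proteins' abundances in one sample. For each pair the
reference samples define a robust location/scale — the median and the raw
(unscaled) median absolute deviation — and every test sample is standardized
with the modified z score

    Mi = 0.6745 * (x - median) / MAD.

The constant 0.6745 = 1/Phi^-1(0.75) is the normal-consistency factor that
puts MAD-unit deviations on the standard-normal scale; because it is applied
here the MAD itself must stay unscaled (a 1.4826-scaled MAD would correct
twice). |Mi| > 3.5 marks the sample as an outlier for that pair, and the
pair's score is the sum of |Mi| over its outlier test samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: normal-consistency factor: deviations in raw-MAD units -> z units
MAD_TO_Z = 0.6745
#: reciprocal convention: scales a raw MAD to a standard-deviation estimate
MAD_SCALE = 1.4826

#: outlier threshold on |Mi| (strict inequality)
DEFAULT_Z_THRESHOLD = 3.5


def modified_z(x, ref_median, ref_mad):
    """Modified z score ``0.6745 * (x - ref_median) / ref_mad``.

    Accepts scalars or arrays (broadcasting); ``ref_mad`` must be > 0 —
    degenerate pairs are the caller's responsibility to filter.
    """
    mad = np.asarray(ref_mad, dtype=float)
    if np.any(mad <= 0) or np.any(np.isnan(mad)):
        raise ValueError("ref_mad must be strictly positive")
    out = MAD_TO_Z * (np.asarray(x, dtype=float) - np.asarray(ref_median, dtype=float)) / mad
    if out.ndim == 0:
        return float(out)
    return out


def compute_log_ratios(matrix: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-pair, per-sample log ratios (first-alphabetical minus second).

    Only pairs with both proteins measured appear in the result; a ratio is
    missing in a sample iff either protein is missing there.
    """
    measured = pairs[pairs["protein_a"].isin(matrix.index)
                     & pairs["protein_b"].isin(matrix.index)]
    if measured.empty:
        return pd.DataFrame(index=pd.Index([], name="pair"),
                            columns=matrix.columns, dtype=float)
    a = matrix.loc[measured["protein_a"]].to_numpy(dtype=float)
    b = matrix.loc[measured["protein_b"]].to_numpy(dtype=float)
    return pd.DataFrame(a - b, index=measured.index, columns=matrix.columns)


def _nan_median_mad(values: np.ndarray):
    """Row-wise median, raw MAD and non-missing count, NaN-tolerant."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(values, axis=1)
        mad = np.nanmedian(np.abs(values - med[:, None]), axis=1)
    n = np.sum(~np.isnan(values), axis=1)
    return med, mad, n


def reference_stats(ratios: pd.DataFrame, ref_samples,
                    min_ref_obs: int = 5) -> pd.DataFrame:
    """Reference median / raw MAD per pair.

    A pair is ``testable`` only with at least ``min_ref_obs`` non-missing
    reference ratios and a strictly positive MAD; degenerate (MAD = 0)
    pairs are carried along untestable rather than patched with an epsilon,
    which would manufacture unbounded z scores.
    """
    if min_ref_obs < 3:
        raise ValueError("min_ref_obs must be >= 3")
    ref = ratios.loc[:, list(ref_samples)].to_numpy(dtype=float)
    med, mad, n = _nan_median_mad(ref)
    testable = (n >= min_ref_obs) & (mad > 0)
    return pd.DataFrame({"ref_median": med, "ref_mad": mad, "n_ref_obs": n,
                         "testable": testable}, index=ratios.index)


def mi_matrix(ratios: pd.DataFrame, ref_stats: pd.DataFrame,
              samples) -> pd.DataFrame:
    """Modified z scores of testable pairs over the given samples."""
    testable = ref_stats.index[ref_stats["testable"]]
    sub = ratios.loc[testable, list(samples)]
    st = ref_stats.loc[testable]
    mi = modified_z(sub.to_numpy(dtype=float),
                    st["ref_median"].to_numpy()[:, None],
                    st["ref_mad"].to_numpy()[:, None])
    return pd.DataFrame(mi, index=testable, columns=list(samples))


@dataclass
class OutlierCalls:
    """Per-pair modified z scores in test samples, outlier flags and the
    summed score (sum of |Mi| over flagged samples)."""

    mi: pd.DataFrame         # testable pairs x test samples
    flags: pd.DataFrame      # boolean, same shape (missing -> False)
    scores: pd.Series        # per testable pair
    z_threshold: float

    def flagged_samples(self, pair) -> list:
        row = self.flags.loc[pair]
        return list(row.index[row])


def call_outliers(ratios: pd.DataFrame, ref_stats: pd.DataFrame, test_samples,
                  z_threshold: float = DEFAULT_Z_THRESHOLD) -> OutlierCalls:
    """Flag test samples with |Mi| strictly above ``z_threshold`` and sum the
    flagged magnitudes into the pair score (0 iff nothing is flagged)."""
    mi = mi_matrix(ratios, ref_stats, test_samples)
    absmi = mi.abs()
    flags = (absmi > z_threshold).fillna(False)
    scores = absmi.where(flags, 0.0).sum(axis=1)
    return OutlierCalls(mi=mi, flags=flags, scores=scores,
                        z_threshold=z_threshold)


@dataclass
class NormalityDiagnostic:
    """Shapiro–Wilk screen of per-pair reference ratios: the method assumes
    these are approximately normal."""

    p_values: pd.Series       # per tested pair
    fraction_normal: float    # share of tested pairs with p > alpha
    n_constant: int           # pairs excluded for zero variance
    alpha: float


def normality_diagnostic(ratios: pd.DataFrame, ref_samples,
                         alpha: float = 0.05) -> NormalityDiagnostic:
    """Shapiro–Wilk test on each pair's non-missing reference ratios.

    Pairs with fewer than 3 observations are skipped; constant-valued pairs
    are excluded from the fraction and counted separately.
    """
    ref = ratios.loc[:, list(ref_samples)]
    pvals = {}
    n_constant = 0
    for pair, row in ref.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 3:
            continue
        if np.ptp(vals) == 0:
            n_constant += 1
            continue
        pvals[pair] = sps.shapiro(vals).pvalue
    p = pd.Series(pvals, dtype=float, name="shapiro_p")
    frac = float((p > alpha).mean()) if len(p) else float("nan")
    return NormalityDiagnostic(p_values=p, fraction_normal=frac,
                               n_constant=n_constant, alpha=alpha)
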