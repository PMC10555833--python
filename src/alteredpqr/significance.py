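"""Randomized-background significance for pair scores.

The null distribution of the summed outlier score is estimated by scoring
random protein pairs whose "measurements" are resampled reference values:
each slot of a random pair picks a random analyzed protein, permutes that
protein's reference values across its non-missing reference positions, and
fills its non-missing test positions with draws (with replacement) from the
same reference values. This preserves each protein's marginal reference
variability and missingness while destroying both pair structure and any
genuine test-sample signal. A gamma distribution is fitted to the retained
background scores by matching moments and real scores are converted to
upper-tail p-values, then Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DEFAULT_Z_THRESHOLD, call_outliers, reference_stats

logger = logging.getLogger("alteredpqr")

#: if more than this share of background scores is exactly 0, the gamma fit
#: is abandoned for a rank-based empirical p-value
ZERO_FRACTION_FALLBACK = 0.95

_MIN_P = 1e-300


@dataclass
class BackgroundModel:
    """Simulated random-pair score sample with its fitted gamma null."""

    scores: np.ndarray
    gamma_shape: float
    gamma_rate: float
    n_background_pairs: int
    seed: int
    empirical: bool = False
    zero_fraction: float = field(default=float("nan"))


def fit_gamma_moments(scores) -> tuple[float, float]:
    """Gamma (shape, rate) by matching moments: shape = m²/v, rate = m/v,
    with m the sample mean and v the sample variance (ddof=1)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")
    m = float(scores.mean())
    v = float(scores.var(ddof=1))
    if v <= 0:
        raise ValueError("background scores have zero variance")
    if m <= 0:
        raise ValueError("background scores have non-positive mean")
    return m * m / v, m / v


def _draw_slot(ref: np.ndarray, test: np.ndarray, idx: np.ndarray,
               rng: np.random.Generator):
    """Resampled (ref, test) value blocks for the chosen slot proteins.

    Row k of the output holds protein ``idx[k]``'s reference values permuted
    across its non-missing reference positions, and test positions filled
    with replacement draws from those reference values. Missing positions of
    the slot protein stay missing.
    """
    n = len(idx)
    n_ref, n_test = ref.shape[1], test.shape[1]
    if not (np.isnan(ref).any() or np.isnan(test).any()):
        # fast path: permute columns per row via random-key argsort
        perm = np.argsort(rng.random((n, n_ref)), axis=1)
        ref_out = ref[idx[:, None], perm]
        draw = rng.integers(0, n_ref, size=(n, n_test))
        test_out = ref[idx[:, None], draw]
        return ref_out, test_out
    ref_out = np.full((n, n_ref), np.nan)
    test_out = np.full((n, n_test), np.nan)
    for k, i in enumerate(idx):
        rvals = ref[i]
        rpos = np.flatnonzero(~np.isnan(rvals))
        if len(rpos) == 0:
            continue
        pool = rvals[rpos]
        ref_out[k, rpos] = rng.permutation(pool)
        tpos = np.flatnonzero(~np.isnan(test[i]))
        if len(tpos):
            test_out[k, tpos] = rng.choice(pool, size=len(tpos), replace=True)
    return ref_out, test_out


def build_background(matrix: pd.DataFrame, ref_samples, test_samples,
                     analyzed_proteins, n_pairs: int, seed: int,
                     z_threshold: float = DEFAULT_Z_THRESHOLD,
                     min_ref_obs: int = 5) -> BackgroundModel:
    """Score ``n_pairs`` random resampled pairs through the full outlier-
    calling path and fit the gamma null by matching moments.

    ``analyzed_proteins`` should be the proteins appearing in testable real
    pairs, so the background shares their measurement characteristics.
    """
    if n_pairs < 200:
        raise ValueError("n_pairs must be >= 200 for a stable null")
    prots = sorted(set(analyzed_proteins) & set(matrix.index))
    if len(prots) < 2:
        raise ValueError("need at least 2 analyzed proteins")
    sub = matrix.loc[prots]
    ref = sub.loc[:, list(ref_samples)].to_numpy(dtype=float)
    test = sub.loc[:, list(test_samples)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    npro = len(prots)
    i = rng.integers(0, npro, size=n_pairs)
    j = (i + rng.integers(1, npro, size=n_pairs)) % npro  # distinct partner

    ref_a, test_a = _draw_slot(ref, test, i, rng)
    ref_b, test_b = _draw_slot(ref, test, j, rng)
    cols = [f"r{k}" for k in range(ref.shape[1])] + \
           [f"t{k}" for k in range(test.shape[1])]
    ratios = pd.DataFrame(np.hstack([ref_a - ref_b, test_a - test_b]),
                          index=pd.RangeIndex(n_pairs), columns=cols)
    ref_cols = cols[:ref.shape[1]]
    test_cols = cols[ref.shape[1]:]
    stats = reference_stats(ratios, ref_cols, min_ref_obs=min_ref_obs)
    calls = call_outliers(ratios, stats, test_cols, z_threshold=z_threshold)
    scores = calls.scores.to_numpy(dtype=float)
    if len(scores) < 50:
        raise ValueError(
            f"only {len(scores)} testable background pairs; increase n_pairs")
    zero_fraction = float((scores == 0).mean())
    if zero_fraction > ZERO_FRACTION_FALLBACK:
        logger.warning("background is %.1f%% zeros; falling back to an "
                       "empirical rank p-value", 100 * zero_fraction)
        return BackgroundModel(scores=scores, gamma_shape=float("nan"),
                               gamma_rate=float("nan"),
                               n_background_pairs=n_pairs, seed=seed,
                               empirical=True, zero_fraction=zero_fraction)
    if scores.var(ddof=1) <= 0:
        raise ValueError("background scores have zero variance")
    shape, rate = fit_gamma_moments(scores)
    return BackgroundModel(scores=scores, gamma_shape=shape, gamma_rate=rate,
                           n_background_pairs=n_pairs, seed=seed,
                           empirical=False, zero_fraction=zero_fraction)


def score_pvalue(score, model: BackgroundModel):
    """Upper-tail p-value P(X >= score) under the fitted null; non-positive
    scores map to p = 1. Returns a float for scalar input."""
    s = np.atleast_1d(np.asarray(score, dtype=float))
    if model.empirical:
        bg = np.sort(model.scores)
        n = len(bg)
        ge = n - np.searchsorted(bg, s, side="left")
        p = (1.0 + ge) / (n + 1.0)
    else:
        p = sps.gamma.sf(s, a=model.gamma_shape,
                         scale=1.0 / model.gamma_rate)
    p = np.where(s <= 0, 1.0, np.clip(p, _MIN_P, 1.0))
    return float(p[0]) if np.isscalar(score) or np.ndim(score) == 0 else p


def bh_adjust(p_values):
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_table(scores: pd.Series, model: BackgroundModel,
                       adj_p_threshold: float = 0.1,
                       top_fraction: float = 0.01) -> pd.DataFrame:
    """Per-pair significance: p, BH-adjusted p, score percentile, the
    ``significant`` call (adj p < threshold) and an advisory ``top_score``
    flag marking the ceil(top_fraction · n) highest scores (ties broken by
    smaller p, then pair ID)."""
    s = scores.to_numpy(dtype=float)
    p = np.atleast_1d(score_pvalue(s, model))
    adj = bh_adjust(p)
    pct = 100.0 * sps.rankdata(s, method="max") / len(s) if len(s) else []
    out = pd.DataFrame({"score": s, "p_value": p, "adj_p_value": adj,
                        "rank_percentile": pct}, index=scores.index)
    out["significant"] = out["adj_p_value"] < adj_p_threshold
    k = math.ceil(top_fraction * len(out)) if len(out) else 0
    order = out.assign(_pair=list(out.index)).sort_values(
        ["score", "p_value", "_pair"], ascending=[False, True, True]).index
    out["top_score"] = False
    out.loc[order[:k], "top_score"] = True
    return out
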