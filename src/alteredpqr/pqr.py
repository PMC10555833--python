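"""The pair-ratio outlier screen, end to end.

:class:`AlteredPQR` is fit-shaped: ``fit`` learns, from the reference
samples, each pair's robust ratio distribution (median / raw MAD) and the
randomized-background gamma null, then scores the test samples; ``predict``
returns the per-pair outlier flags and ``transform`` the modified-z matrix,
both usable on new sample columns against the fitted reference statistics.

Filters run in a fixed order: annotation exclusions → reference-variability
filters → significance (gamma p, BH) → contribution test and redundancy
resolution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import filters as flt
from .core import (DEFAULT_Z_THRESHOLD, call_outliers, compute_log_ratios,
                   mi_matrix, normality_diagnostic, reference_stats)
from .corshift import group_correlation
from .io import design_groups, validate_design, validate_quant_matrix
from .significance import build_background, significance_table

logger = logging.getLogger("alteredpqr")


class AlteredPQR(BaseEstimator):
    """Detect protein pairs whose quantitative ratio is an outlier in test
    samples relative to a reference sample group.

    Parameters
    ----------
    z_threshold : float, default 3.5
        Strict |Mi| cutoff declaring a test-sample ratio an outlier.
    single_z_threshold : float, default 2.0
        Looser single-protein |Mi| cutoff used by the contribution test.
    adj_p_threshold : float, default 0.1
        BH-adjusted p cutoff for the ``significant`` call.
    min_ref_obs : int, default 5
        Minimum non-missing reference ratios for a pair to be testable.
    n_background_pairs : int or None
        Random background pairs for the gamma null; ``None`` uses
        10× the number of testable pairs, floor 1000.
    variability_filter : bool, default True
        Apply the reference-variability filters (calibrated for small
        reference sets).
    max_ref_outlier_samples : int, default 3
        Deviant reference samples that disqualify a pair/protein; with
        ``fractional_ref_outliers`` the cutoff is ceil(0.3·n_ref) instead.
    protein_mad_mult : float, default 2.0
        Multiplier in the protein-level bound median ± 1.4826·mult·MAD.
    resolve_redundancy : bool, default True
        Collapse each contributing protein onto its highest-scoring pair.
    top_fraction : float, default 0.01
        Advisory top-score flag (the "top 1%" heuristic).
    random_state : int, default 0
        Seed for the background resampling (echoed in outputs).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per analyzed pair: proteins, score, p, adjusted p, score
        percentile, flags, filter status and representative pair.
    ratios_, ref_stats_, mi_, flags_, scores_ : per-pair intermediates.
    background_ : BackgroundModel
    filter_report_ : pandas.DataFrame  (status / reason / representative)
    diagnostics like ``n_testable_``, ``n_significant_``.
    """

    def __init__(self, z_threshold: float = DEFAULT_Z_THRESHOLD,
                 single_z_threshold: float = 2.0,
                 adj_p_threshold: float = 0.1, min_ref_obs: int = 5,
                 n_background_pairs: int | None = None,
                 variability_filter: bool = True,
                 max_ref_outlier_samples: int = 3,
                 fractional_ref_outliers: bool = False,
                 protein_mad_mult: float = 2.0,
                 resolve_redundancy: bool = True,
                 top_fraction: float = 0.01, random_state: int = 0):
        self.z_threshold = z_threshold
        self.single_z_threshold = single_z_threshold
        self.adj_p_threshold = adj_p_threshold
        self.min_ref_obs = min_ref_obs
        self.n_background_pairs = n_background_pairs
        self.variability_filter = variability_filter
        self.max_ref_outlier_samples = max_ref_outlier_samples
        self.fractional_ref_outliers = fractional_ref_outliers
        self.protein_mad_mult = protein_mad_mult
        self.resolve_redundancy = resolve_redundancy
        self.top_fraction = top_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, design: pd.DataFrame, pairs: pd.DataFrame,
            exclusions=()):
        """Run the full screen.

        ``X`` is the protein × sample log-abundance matrix, ``design`` the
        sample table (``group`` ∈ reference/test), ``pairs`` a canonical
        pair table (see :func:`alteredpqr.io.make_pairs`), ``exclusions``
        an iterable of :class:`alteredpqr.io.ExclusionList`.
        """
        X = validate_quant_matrix(X)
        design = validate_design(design.loc[design.index.intersection(X.columns)])
        ref_samples, test_samples = design_groups(design, X)
        self.ref_samples_, self.test_samples_ = ref_samples, test_samples

        report = pd.DataFrame({
            "status": flt.STATUS_KEPT, "reason": "", "representative": ""},
            index=pairs.index)
        report.loc[~pairs["measured"], "status"] = "unmeasured"

        ann = flt.annotation_filter(pairs, exclusions)
        excluded = ann.index[ann["status"] == flt.STATUS_ANNOTATION]
        report.loc[excluded, "status"] = flt.STATUS_ANNOTATION
        report.loc[excluded, "reason"] = ann.loc[excluded, "reason"]

        work = pairs[pairs["measured"]
                     & (report["status"] != flt.STATUS_ANNOTATION)]
        self.ratios_ = compute_log_ratios(X, work)
        self.ref_stats_ = reference_stats(self.ratios_, ref_samples,
                                          min_ref_obs=self.min_ref_obs)
        untestable = self.ref_stats_.index[~self.ref_stats_["testable"]]
        report.loc[untestable, "status"] = "untestable"

        if self.variability_filter:
            var_status = flt.reference_variability_filter(
                self.ratios_, self.ref_stats_,
                work.loc[work.index.difference(untestable)], X, ref_samples,
                z_threshold=self.z_threshold,
                max_ref_outlier_samples=self.max_ref_outlier_samples,
                protein_mad_mult=self.protein_mad_mult,
                fractional=self.fractional_ref_outliers)
            removed = var_status.index[var_status != flt.STATUS_KEPT]
            report.loc[removed, "status"] = var_status.loc[removed]

        keep = report.loc[self.ref_stats_.index, "status"] == flt.STATUS_KEPT
        kept_idx = self.ref_stats_.index[keep
                                         & self.ref_stats_["testable"]]
        stats_kept = self.ref_stats_.loc[kept_idx]
        calls = call_outliers(self.ratios_.loc[kept_idx], stats_kept,
                              test_samples, z_threshold=self.z_threshold)
        self.mi_ = calls.mi
        self.flags_ = calls.flags
        self.scores_ = calls.scores
        self.n_testable_ = len(kept_idx)
        if self.n_testable_ == 0:
            raise ValueError("no testable pairs after filtering")

        work_kept = work.loc[kept_idx]
        analyzed = sorted(set(work_kept["protein_a"])
                          | set(work_kept["protein_b"]))
        self.analyzed_proteins_ = analyzed
        n_bg = self.n_background_pairs or max(1000, 10 * self.n_testable_)
        self.background_ = build_background(
            X, ref_samples, test_samples, analyzed, n_pairs=n_bg,
            seed=int(self.random_state), z_threshold=self.z_threshold,
            min_ref_obs=self.min_ref_obs)

        sig = significance_table(self.scores_, self.background_,
                                 adj_p_threshold=self.adj_p_threshold,
                                 top_fraction=self.top_fraction)

        # contribution + redundancy among significant pairs
        sig_idx = sig.index[sig["significant"]]
        contributors = {}
        if len(sig_idx):
            prots = set(work.loc[sig_idx, "protein_a"]) \
                | set(work.loc[sig_idx, "protein_b"])
            self.protein_profiles_ = flt.protein_outlier_profiles(
                X, ref_samples, test_samples, proteins=prots,
                min_ref_obs=self.min_ref_obs)
            for pair in sig_idx:
                contributors[pair] = flt.contribution_test(
                    calls.flagged_samples(pair),
                    work.at[pair, "protein_a"], work.at[pair, "protein_b"],
                    self.protein_profiles_, self.single_z_threshold)
        self.contributors_ = contributors
        if self.resolve_redundancy and len(sig_idx):
            red = flt.select_representative_pairs(
                sig.loc[sig_idx, ["score", "adj_p_value"]], contributors)
            merged = red.index[red["status"] == flt.STATUS_MERGED]
            report.loc[merged, "status"] = flt.STATUS_MERGED
            report.loc[merged, "representative"] = \
                red.loc[merged, "representative"]

        results = pd.concat(
            [work.loc[kept_idx, ["protein_a", "protein_b"]], sig], axis=1)
        results["n_flagged"] = self.flags_.sum(axis=1).astype(int)
        results["flagged_samples"] = [
            ";".join(calls.flagged_samples(p)) for p in results.index]
        results["contributors"] = [
            ";".join(sorted(contributors.get(p, set())))
            for p in results.index]
        results["status"] = report.loc[results.index, "status"]
        results["representative"] = report.loc[results.index,
                                               "representative"]
        self.results_ = results.sort_values(
            ["adj_p_value", "p_value", "score", "protein_a"],
            ascending=[True, True, False, True])
        self.filter_report_ = report
        self.n_significant_ = int(sig["significant"].sum())
        self.n_representative_ = int(
            (results["significant"]
             & (results["status"] == flt.STATUS_KEPT)).sum())
        self._X_fit = X
        self._pairs_fit = work_kept
        logger.info("AlteredPQR: %d pairs in, %d testable, %d significant, "
                    "%d after redundancy resolution", len(pairs),
                    self.n_testable_, self.n_significant_,
                    self.n_representative_)
        return self

    # -------------------------------------------------------- fitted access
    def significant_pairs(self, resolved: bool = True) -> pd.DataFrame:
        """Significant pairs, optionally only redundancy-resolved ones."""
        check_is_fitted(self, "results_")
        out = self.results_[self.results_["significant"]]
        if resolved:
            out = out[out["status"] == flt.STATUS_KEPT]
        return out

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Modified-z matrix (testable kept pairs × samples).

        With ``X=None``, the fitted test samples; otherwise the columns of
        ``X`` are scored against the fitted reference statistics.
        """
        check_is_fitted(self, "results_")
        if X is None:
            return self.mi_
        ratios = compute_log_ratios(X, self._pairs_fit)
        return mi_matrix(ratios, self.ref_stats_.loc[ratios.index],
                         list(X.columns))

    def predict(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Boolean outlier flags (|Mi| > z_threshold) per pair × sample."""
        mi = self.transform(X)
        return (mi.abs() > self.z_threshold).fillna(False)

    def normality(self, alpha: float = 0.05):
        """Shapiro–Wilk diagnostic of reference ratio normality."""
        check_is_fitted(self, "results_")
        return normality_diagnostic(self.ratios_, self.ref_samples_, alpha)

    def outlier_pair_correlations(self, min_obs: int = 3) -> pd.DataFrame:
        """Diagnostic correlations for significant pairs: Pearson r of the
        two proteins' expression in reference samples, in all test samples,
        and in the pair's outlier samples alone (NaN below ``min_obs``)."""
        check_is_fitted(self, "results_")
        sig = self.significant_pairs(resolved=False)
        rows = []
        for pair, row in sig.iterrows():
            sub = self._pairs_fit.loc[[pair]]
            r_ref, _ = group_correlation(self._X_fit, sub,
                                         self.ref_samples_, min_obs)
            r_test, _ = group_correlation(self._X_fit, sub,
                                          self.test_samples_, min_obs)
            flagged = row["flagged_samples"].split(";") \
                if row["flagged_samples"] else []
            r_out = np.nan
            if len(flagged) >= min_obs:
                r_out = group_correlation(self._X_fit, sub, flagged,
                                          min_obs)[0][0]
            rows.append((pair, r_ref[0], r_test[0], r_out))
        return pd.DataFrame(rows, columns=["pair", "r_reference", "r_test",
                                           "r_outlier_samples"]
                            ).set_index("pair")


def run_pqr(matrix: pd.DataFrame, design: pd.DataFrame, pairs: pd.DataFrame,
            exclusions=(), **params) -> pd.DataFrame:
    """One-call wrapper: fit :class:`AlteredPQR` and return its results."""
    return AlteredPQR(**params).fit(matrix, design, pairs,
                                    exclusions=exclusions).results_
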