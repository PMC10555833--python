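"""Reference-variability filters, annotation exclusions and redundancy
resolution.

Two conventions coexist here and must not be mixed: the pair-level modified
z uses the 0.6745 factor on a raw MAD, while the protein-level variability
bound scales the raw MAD with 1.4826 (its reciprocal) into a standard-
deviation estimate — median ± 1.4826 · mult · MAD.

Redundancy resolution keeps, for every protein that demonstrably
contributes to its pairs' outlier signal (single-protein |Mi| > 2 in at
least half of a pair's outlier samples), only that protein's highest-
scoring pair, so one dysregulated hub is reported once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (DEFAULT_Z_THRESHOLD, MAD_SCALE, OutlierCalls, _nan_median_mad,
                   mi_matrix, modified_z)

logger = logging.getLogger("alteredpqr")

STATUS_KEPT = "kept"
STATUS_VAR_PAIR = "removed_variability_pair"
STATUS_VAR_PROTEIN = "removed_variability_protein"
STATUS_ANNOTATION = "removed_annotation"
STATUS_MERGED = "merged_into_representative"


def ref_outlier_cutoff(n_ref: int, max_ref_outlier_samples: int = 3,
                       fractional: bool = False) -> int:
    """Number of deviant reference samples that disqualifies a pair/protein.

    The fixed default of 3 matches a 10-sample reference set; the fractional
    mode (ceil(0.3 · n_ref)) rescales it for other reference sizes.
    """
    if fractional:
        return max(1, math.ceil(0.3 * n_ref))
    return max_ref_outlier_samples


def variable_reference_pairs(ratios: pd.DataFrame, ref_stats: pd.DataFrame,
                             ref_samples, z_threshold: float = DEFAULT_Z_THRESHOLD,
                             cutoff: int = 3) -> pd.Index:
    """Pairs whose own reference ratios are outliers (|Mi| > threshold,
    scored against the full reference median/MAD) in >= ``cutoff`` reference
    samples."""
    mi_ref = mi_matrix(ratios, ref_stats, ref_samples).abs()
    counts = (mi_ref > z_threshold).sum(axis=1)
    return counts.index[counts >= cutoff]


def variable_proteins(matrix: pd.DataFrame, ref_samples, proteins=None,
                      protein_mad_mult: float = 2.0, cutoff: int = 3) -> set:
    """Proteins whose reference log quantities stray outside
    median ± 1.4826 · mult · MAD in >= ``cutoff`` reference samples.

    With MAD = 0 the band collapses onto the median and any differing value
    counts as outside it (this flags e.g. a cleanly bimodal protein).
    """
    sub = matrix if proteins is None else matrix.loc[sorted(set(proteins))]
    vals = sub.loc[:, list(ref_samples)].to_numpy(dtype=float)
    med, mad, n = _nan_median_mad(vals)
    bound = MAD_SCALE * protein_mad_mult * mad
    dev = np.abs(vals - med[:, None])
    outside = dev > bound[:, None]          # NaN devs compare False
    counts = np.nansum(outside, axis=1)
    flagged = (n > 0) & (counts >= cutoff)
    return set(sub.index[flagged])


def reference_variability_filter(ratios: pd.DataFrame, ref_stats: pd.DataFrame,
                                 pairs: pd.DataFrame, matrix: pd.DataFrame,
                                 ref_samples,
                                 z_threshold: float = DEFAULT_Z_THRESHOLD,
                                 max_ref_outlier_samples: int = 3,
                                 protein_mad_mult: float = 2.0,
                                 fractional: bool = False) -> pd.Series:
    """Status per pair: ``removed_variability_pair`` when the pair's own
    reference ratios are repeatedly deviant, ``removed_variability_protein``
    when the pair contains a highly variable protein, else ``kept``."""
    cutoff = ref_outlier_cutoff(len(list(ref_samples)),
                                max_ref_outlier_samples, fractional)
    status = pd.Series(STATUS_KEPT, index=pairs.index, name="status")
    bad_pairs = variable_reference_pairs(ratios, ref_stats, ref_samples,
                                         z_threshold, cutoff)
    status.loc[status.index.intersection(bad_pairs)] = STATUS_VAR_PAIR
    prots = set(pairs["protein_a"]) | set(pairs["protein_b"])
    bad_prots = variable_proteins(matrix, ref_samples,
                                  proteins=prots & set(matrix.index),
                                  protein_mad_mult=protein_mad_mult,
                                  cutoff=cutoff)
    hit = (pairs["protein_a"].isin(bad_prots)
           | pairs["protein_b"].isin(bad_prots))
    status.loc[hit & (status == STATUS_KEPT)] = STATUS_VAR_PROTEIN
    return status


def annotation_filter(pairs: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Status/reason per pair under the exclusion lists; a pair containing a
    protein on any list is ``removed_annotation`` with every triggering
    list's reason recorded."""
    status = pd.Series(STATUS_KEPT, index=pairs.index, name="status")
    reason = pd.Series("", index=pairs.index, name="reason")
    for excl in exclusions:
        ids = set(excl.protein_ids)
        hit = pairs["protein_a"].isin(ids) | pairs["protein_b"].isin(ids)
        status.loc[hit] = STATUS_ANNOTATION
        tagged = reason.loc[hit]
        reason.loc[hit] = np.where(tagged == "", excl.reason,
                                   tagged + ";" + excl.reason)
    return pd.DataFrame({"status": status, "reason": reason})


@dataclass
class ProteinOutlierProfiles:
    """Single-protein modified z scores in test samples, against each
    protein's own reference median/raw MAD. Proteins with degenerate
    reference spread (MAD = 0) carry NaN rows and can never contribute."""

    mi: pd.DataFrame        # proteins x test samples (NaN where degenerate)
    ref_median: pd.Series
    ref_mad: pd.Series
    n_degenerate: int


def protein_outlier_profiles(matrix: pd.DataFrame, ref_samples, test_samples,
                             proteins=None,
                             min_ref_obs: int = 5) -> ProteinOutlierProfiles:
    """Per-protein Mi of the log quantity itself (not a ratio)."""
    sub = matrix if proteins is None else matrix.loc[sorted(set(proteins))]
    ref = sub.loc[:, list(ref_samples)].to_numpy(dtype=float)
    med, mad, n = _nan_median_mad(ref)
    ok = (mad > 0) & (n >= min_ref_obs)
    test = sub.loc[:, list(test_samples)].to_numpy(dtype=float)
    mi = np.full_like(test, np.nan)
    if ok.any():
        mi[ok] = modified_z(test[ok], med[ok][:, None], mad[ok][:, None])
    return ProteinOutlierProfiles(
        mi=pd.DataFrame(mi, index=sub.index, columns=list(test_samples)),
        ref_median=pd.Series(med, index=sub.index),
        ref_mad=pd.Series(mad, index=sub.index),
        n_degenerate=int((~ok).sum()))


def contribution_test(flagged_samples, protein_a: str, protein_b: str,
                      profiles: ProteinOutlierProfiles,
                      single_z_threshold: float = 2.0) -> set:
    """Proteins of a flagged pair that drive its signal.

    A protein contributes iff its own |Mi| exceeds ``single_z_threshold``
    in at least half of the pair's outlier samples (count >= flagged/2, so
    2 of 4 and 2 of 3 pass, 1 of 3 fails). Both proteins can contribute —
    the mild-but-opposite-shift case. Returns a subset of {a, b}.
    """
    flagged = list(flagged_samples)
    if not flagged:
        return set()
    need = len(flagged) / 2.0
    out = set()
    for prot in (protein_a, protein_b):
        if prot not in profiles.mi.index:
            continue
        vals = profiles.mi.loc[prot, flagged].to_numpy(dtype=float)
        hits = np.nansum(np.abs(vals) > single_z_threshold)
        if hits >= need:
            out.add(prot)
    return out


def select_representative_pairs(significant: pd.DataFrame,
                                contributors: dict) -> pd.DataFrame:
    """Keep one pair per contributing protein: pairs are visited in
    descending (score, -adj p, pair ID) priority; a pair whose contributing
    protein is already represented is merged into that protein's kept pair.
    Pairs with no contributors are kept as-is (flagged ``no_contributor``).

    ``significant`` needs columns ``score`` and ``adj_p_value`` indexed by
    pair; ``contributors`` maps pair -> set of contributing proteins.
    """
    order = significant.assign(_pair=list(significant.index)).sort_values(
        ["score", "adj_p_value", "_pair"],
        ascending=[False, True, True]).index
    rep_of = {}        # contributing protein -> kept pair
    status = pd.Series(STATUS_KEPT, index=significant.index, name="status")
    representative = pd.Series("", index=significant.index,
                               name="representative")
    no_contrib = pd.Series(False, index=significant.index,
                           name="no_contributor")
    for pair in order:
        contrib = sorted(contributors.get(pair, set()))
        if not contrib:
            no_contrib.loc[pair] = True
            continue
        taken = [p for p in contrib if p in rep_of]
        if taken:
            # merge into the highest-priority existing representative
            winners = {rep_of[p] for p in taken}
            winner = sorted(winners,
                            key=lambda q: (-significant.at[q, "score"],
                                           significant.at[q, "adj_p_value"],
                                           q))[0]
            status.loc[pair] = STATUS_MERGED
            representative.loc[pair] = winner
        else:
            for p in contrib:
                rep_of[p] = pair
    return pd.DataFrame({"status": status, "representative": representative,
                         "no_contributor": no_contrib})
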