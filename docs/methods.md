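# Methods

## Model and assumptions

The unit of analysis is the PQR — the per-sample log-ratio of two proteins
known or inferred to form a stable complex. The working assumptions are:

* the input matrix is log-scale (log2 by default; the base is explicit and
  recorded in every run log) with missing values allowed;
* for a co-regulated pair, reference-sample log-ratios are approximately
  normal around a stable value; the Shapiro–Wilk diagnostic
  (`AlteredPQR.normality`, CLI `diagnostics`) quantifies how well a given
  dataset meets this;
* the reference group captures the technical plus biological variability
  against which test samples should be judged, which is why location and
  scale are estimated robustly (median, raw MAD) rather than by mean/sd —
  a few aberrant reference samples must not inflate the scale.

Two MAD conventions coexist deliberately and must never be mixed. The
pair-level and complex-level modified z uses `0.6745 · dev / MAD` with the
*raw* MAD — 0.6745 ≈ Φ⁻¹(0.75) is itself the normal-consistency factor, so
a pre-scaled MAD would correct twice. The protein-level variability filter
instead scales the raw MAD with 1.4826 (the reciprocal) into a
standard-deviation estimate and bounds values at median ± 1.4826·2·MAD.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `z_threshold` | 3.5 | strict \|Mi\| cutoff for a test-sample outlier (Iglewicz–Hoaglin convention) |
| `single_z_threshold` | 2.0 | looser single-protein \|Mi\| cutoff in the contribution test |
| `adj_p_threshold` | 0.1 | BH-adjusted p for the `significant` call |
| `min_ref_obs` | 5 | non-missing reference ratios needed for a pair to be testable |
| `n_background_pairs` | 10× testable, floor 1000 | random pairs for the gamma null; the tail must be estimated beyond the real score range |
| `max_ref_outlier_samples` | 3 | deviant reference samples that disqualify a pair/protein (calibrated to a 10-sample reference; `fractional_ref_outliers` switches to ceil(0.3·n_ref)) |
| `protein_mad_mult` | 2.0 | multiplier in the protein variability bound |
| `top_fraction` | 0.01 | advisory top-score flag, ceil(0.01·n) pairs, ties by smaller p then pair ID |
| CorShift `r_threshold`, `p_threshold`, `delta_threshold` | 0.6, 0.05, 0.6 | significant-correlation and shift-size cutoffs |
| CorShift `min_obs` | 8 | paired observations per group below which a pair is untestable (correlation p-values are fragile at small n) |
| complex `majority_fraction` | 0.5 | a subunit enters the complex median only if measured in strictly more than this share of all samples |
| complex `min_fraction` | 0.10 | inclusive share of evaluable test samples that must be outliers |

All units are log2 abundance unless stated. Every threshold is a CLI flag
and is echoed in `run_log.txt` together with the seed.

## Background null and significance

The null score distribution is built by scoring random protein pairs whose
values are resampled reference measurements: each slot of a random pair
picks a random analyzed protein, permutes that protein's reference values
across its non-missing reference positions, and fills its non-missing test
positions with draws (with replacement) from the same reference values.
Using the slot protein's own reference pool for both position blocks
preserves each protein's marginal variability and missingness while
destroying pair structure and any genuine test-sample signal; mixing
proteins across the two blocks of one slot would inject baseline offsets
and wreck the null. A gamma is fitted to the retained background scores by
matching moments on the sample mean and variance (ddof = 1; at the
mandated background sizes the ddof choice moves the fit by < 0.1%). Zeros
are included in the fit; if more than 95% of background scores are exactly
zero the gamma is abandoned for a rank-based empirical p-value with
pseudocount, and the fallback is logged. p-values are upper-tail gamma
probabilities, floored at 1e-300, with p = 1 for non-positive scores, and
BH-adjusted via statsmodels.

## Numerical and policy choices

* Median of an even count: mean of the two central values (numpy).
* Pairs are unordered; the reported orientation is alphabetical, so ratios
  and Mi signs are deterministic. Swapping orientation negates Mi and
  changes nothing downstream (tested).
* `ref_mad = 0` makes a pair untestable rather than epsilon-patched — an
  epsilon would manufacture unbounded z scores. The same rule makes a
  degenerate protein non-contributing in the contribution test.
* In the protein-level variability filter a zero MAD collapses the band
  onto the median and any differing value counts as outside it; this flags
  cleanly bimodal reference profiles instead of exempting them.
* "At least half" in the contribution test is `count ≥ flagged/2` exactly:
  1 of 3 fails, 2 of 3 and 2 of 4 pass.
* Redundancy resolution walks significant pairs in descending
  (score, −adj p, pair ID) priority; a pair whose contributing protein is
  already represented is merged into that protein's kept pair. Significant
  pairs where neither protein passes the contribution test are kept and
  flagged `no_contributor` — they cannot cause hub redundancy, and
  discarding them would be a silent loss.
* Filters run annotation → variability → significance → redundancy; the
  order is logged. The variability filter is on by default (it exists to
  compensate small reference sets) and switchable for cohorts with many
  reference samples.
* CorShift adjusts p within each group across all testable pairs (matching
  the convention of reporting one adjusted p per group), uses
  pairwise-complete observations, and classifies with strict inequalities
  for r and |Δr| and ≤ for adjusted p.
* The complex scan reports the outlier fraction against both evaluable
  test samples (the deciding one) and all test samples, since a sample
  missing any kept subunit carries no complex value. Direction is the sign
  of the mean flagged Mi.
* Samples assigned to neither reference nor test (e.g. healthy-tissue
  columns in a tumor cohort) are ignored by the main screen; finer
  subtype labels drive CorShift group selection.

## The synthetic-data generator

`simulate_dataset` emulates log2-scale abundances with per-protein
baselines ~ N(20, 2), i.i.d. technical noise (sd 0.25, chosen so null
ratio |Mi| rarely exceeds 3.5), one shared latent factor per complex
(weight 0.15 — mild co-regulation below the noise level), 5% missingness,
and a 10-reference / 24-test layout mirroring a typical cell-line panel.
Injected events — pair-ratio shifts (optionally split oppositely across
both partners), group-specific correlation gains, hub shifts and
complex-wide shifts — are recorded in a ground-truth table keyed to the
emitted pair/protein/complex IDs. What it does **not** emulate:
peptide-level noise, batch effects, intensity-dependent missingness or
heteroscedasticity. A green recovery test therefore establishes that the
statistics behave as designed under the assumed noise model, not that any
particular real cohort meets those assumptions.

## Known limitations

* **Small reference sets make the null heavy-tailed.** With 10 reference
  samples the raw MAD is a noisy scale estimate; measured on simulated
  null data, the per-test-sample outlier rate at |Mi| > 3.5 is ~3.3%
  rather than the nominal ≲ 0.1%, null pair scores have a long tail, and
  the variability filter — whose job is exactly to remove unstable
  pairs — discards ~20% of all pairs at that reference size. Consequences:
  moderate injected shifts (e.g. 8× noise sd in 40% of test samples) rank
  high but are not cleanly separable from the extreme null tail, and BH
  adjustment over ~1000 pairs leaves them short of adjusted p < 0.1. The
  randomized background absorbs this tail into the null, so false-positive
  calls remain controlled (the null-calibration test), at the cost of
  power.
* The CorShift rule's three conjunctive conditions (r > 0.6, adjusted
  p ≤ 0.05, |Δr| > 0.6) have ~70% joint power for a true ρ = 0.8 at group
  sizes 18/23; it is a high-precision, moderate-recall classifier by
  construction.
* Ratios say nothing about absolute stoichiometry; the screen reports
  relative quantitative relationships only.
* No imputation is performed anywhere; missingness propagates to ratios
  and pairwise-complete correlations.
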