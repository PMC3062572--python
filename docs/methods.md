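# Methods

## The assay model

A digital barcode-counting hybridization measures, for each probe *p*
and sample *i*, a nonnegative integer count. The package models the
expected count of a probe as the sum of a specific and a nonspecific
component:

- **target probe g**: `λ = a_g · m · u + b(m) · β_g`
- **positive control j** (spiked at `fmol_j`): `λ = s · fmol_j + b(m) · β_j`
- **negative control**: `λ = b(m) · β_p`

where `m` is the input RNA mass (µg), `a_g` the gene's abundance in
counts per µg, `s` the counts per fmol of spiked transcript, `b(m)` the
baseline nonspecific background, `β_p` a fixed per-probe background
propensity, and `u` a multiplicative replicate factor. Observed counts
are Poisson around `λ`. Key structural facts this encodes:

- target counts are **linear in input mass** above background;
- spike-in counts are **independent of mass**, which is what makes
  positive-control normalization a valid between-sample anchor;
- with no RNA, target probes carry only background and are
  statistically indistinguishable from negative controls;
- replicate noise is Poisson at low counts with a multiplicative
  (lognormal) floor at high counts.

## Normalization

Positive-control scaling divides each sample by its positive-control
sum and multiplies by the mean of those sums. The reference is the
*mean* rather than a designated sample: any positive constant yields
identical relative results downstream, and the mean keeps normalized
counts on the raw scale (and leaves the normalized positive-control
average exactly constant across conditions). Target-sum scaling then
equalizes per-sample target sums, touching only target rows; it is
applied for replicate comparison and life-cycle profiling, where the
mRNA fraction of total RNA may differ between preparations, but *not*
for the mass titration, whose whole point is the mass dependence of
target counts. A norm-state machine (`raw → positive_normalized →
target_sum_normalized`) rejects out-of-order application.
Housekeeping-gene normalization is deliberately a stub: the panel
contains no invariant internal-control genes.

## Background and detection

The negative-control model pools all negative-control values in a
condition (probes × replicates) and sets `T = mean + k·SD` (sample SD,
n−1; default `k = 3`). Pooling is deliberate: with 8 negative probes
and 3 replicates, per-probe SDs are far too unstable, and one threshold
per condition is the quantity of interest. The pooled SD includes
probe-to-probe spread in background propensity, which is why it exceeds
the pure Poisson value.

The deletion-calibrated model uses residual counts of probes whose
target gene has been deleted — a direct measurement of
cross-hybridization, which foreign-sequence negative controls
underestimate for probes targeting a large gene family. The threshold
is the largest residual mean plus `k` times *that gene's* SD (default
`k = 4`); the multiplier applies to the max-attaining gene because the
calibration is a worst-case bound. A rounding policy
(`none | ceil_to_50 | ceil_to_100`) is exposed for conservative
operating cutoffs; the package never rounds silently.

Detection uses strict inequality (a count exactly at threshold is not
detected — "above background" resolved conservatively), and the default
statistic is the replicate-group mean, since detection is reported per
condition, not per replicate.

## QC benchmarks

- Standard curves: OLS of log10(count) on log10(fmol); zero-count
  points are dropped (no log-scale information), never pseudocounted.
- Replicate CV: `100 · SD/mean` with sample SD (n−1); genes with zero
  mean are flagged undefined and excluded from group medians, not
  recorded as zero.
- Titration summary: class-average counts per mass level and
  fold-ratios between levels.
- Concordance: Pearson (Spearman by flag) on flattened gene × group
  pairs, log10 scale by default; pairs with a nonpositive value on
  either side are excluded pairwise with a warning. Pseudocounts were
  rejected because they distort exactly the near-background low end
  where count data are already skewed.

## Stage profiling and pattern classification

Stage profiles are replicate means ± sample SDs of fully normalized
counts, in the canonical order embryo, L1 arrest, 12/24/36/48/60 h,
dauer. "Developing larvae" means the 12–48 h stages; 60 h is excluded
from the larval reference because that time point contains adults and
their early embryos. Fold-changes are ratios of stage-mean averages
(ratio of means, not mean of ratios — stage means are the plotted and
interpreted quantity).

Classification applies explicit rules in precedence order
(below-background, embryo-specific, adult-enriched, arrest-enriched,
larval-peaking, broadly-expressed) against a background threshold `T`
and minimum fold `F_min = 3`. The 3-fold default separates clearly
stage-restricted profiles from replicate noise at the CVs typical of
3 biological replicates; it is configurable, and borderline genes are
expected to be sensitive to it — the emitted peak stage and peak fold
make every call auditable. Ties in peak stage break toward the earlier
stage. Labels are invariant under rescaling all counts and `T` by the
same constant. Probes with known cross-hybridization (e.g. an
*ins-13*-style probe that actually reports an overlapping gene) carry a
specificity flag propagated into all outputs.

## qPCR cross-validation

Standard curves are OLS of Ct on log10(copies) over a genomic-DNA
dilution series (≥ 3 points spanning ≥ 2 decades; negative slope
required); efficiency `E = 10^(−1/slope)`, flagged if outside (1, 2.2].
Copies convert back via `10^((ct − intercept)/slope)`; extrapolation
beyond the fitted range is flagged, not forbidden. Reference
normalization divides by the **geometric mean** of the reference-gene
copies per sample (scale-symmetric, the standard multi-reference
convention), rescaled so the across-sample mean factor is 1 — constant
references make it an identity. Cross-platform profile comparison
scales each platform's per-gene profile to its own mean before
correlating on the log scale, because counts and copy numbers are in
incommensurate units; stages where one platform moves ≥ 2-fold and the
other < 1.3-fold are flagged as platform-discordant.

## Synthetic-data generator: calibration and defaults

Defaults are fixed to reproduce the magnitudes of a real 43-target
insulin-like panel and are not tuned per run:

| parameter | default | rationale |
|---|---|---|
| panel | 43 targets, 10 positives, 8 negatives | the insulin-like code set design |
| gene abundances `a_g` | lognormal, median 1400/µg, σ = 1.0 (mean ≈ 2300/µg) | reproduces mean target counts ≈ 240 / 2300 / 23000 at 0.1/1/10 µg and a median technical CV ≈ 8% at 0.1 µg |
| spike ladder | 0.1 × 2^k fmol, k = 0..9, at 550 counts/fmol | positive average ≈ 5650; the 0.1 fmol spike sits near the detection limit |
| background `b0` | 24 counts, flat to 1 µg, doubling log-linearly to 10 µg | negatives flat (~24) below 1 µg, ~2× at 10 µg |
| probe background propensity | lognormal, CV 0.25 | pooled negative SD ≈ 8 at mean 25, hence mean+3SD cutoffs ≈ 49 |
| technical CV τ | 0.015 | the observed CV floor at saturating counts is ~1.8%, far above pure Poisson — a multiplicative pipetting/efficiency term |
| biological CV | 0.20 | biological replicates are several-fold noisier than technical ones (median CV ~17% vs ~8.5% at 0.1 µg) |
| residual cross-hybridization ρ | 0.05 | deletion-strain residuals of ~5% of wild-type signal for the worst probes |

The noise is compound Poisson-lognormal: Poisson for molecule counting,
a per-replicate lognormal factor (technical) on specific signal, plus an
independent per-gene lognormal factor between biological replicates.
The technical factor applies to targets only, so positive-control
normalization does not absorb it — consistent with a CV floor that
survives normalization.

The life-cycle generator plants every pattern class (2 embryo-specific,
1 adult-enriched, 7 arrest-enriched, a sod-3-like gene 10× up in L1
arrest and 30× in dauer vs developing larvae, 2 larval-peaking, 6
below-background, remainder broad) at 3 µg input with 3 biological
replicates per stage. Planted stage totals are equalized by adjusting
only the broadly-expressed genes (whole-organism mRNA composition is
roughly stage-invariant per µg of total RNA); this keeps target-sum
normalization from distorting the planted stage-specific fold-changes,
and the adjusted broad genes stay comfortably inside the broad-class
definition. Deletion strains replace the deleted gene's specific signal
with ρ times itself — residual cross-hybridization scales with the
gene's own wild-type expression, the simplest mechanism consistent with
low-expressing deletions dropping to negative-control level while
high-expressing ones retain ~100+ counts.

What the generator does **not** emulate: sequence-level
cross-hybridization between specific family members, cartridge/lane
batch effects, count saturation at very high totals, and any real
biological covariance between genes. Passing tests therefore
demonstrate the pipeline's arithmetic and statistical behavior under
the assay's stated noise structure, not robustness to artifacts absent
from the model.

## Numerical and design choices

- Delimited text everywhere; numeric formatting uses `%.12g`, which
  round-trips this data's dynamic range exactly.
- Missing values are disallowed in raw counts (digital counting has no
  missingness mechanism); a three-sheet workbook reader (raw /
  replicate means / SDs) imports supplementary-style spreadsheets
  verbatim, with the caller declaring the raw sheet's normalization
  state, which the source workbooks do not record.
- All randomness flows through `numpy.random.Generator` seeded from the
  config; gene-level truth uses a dedicated stream so the same config
  yields the same panel regardless of which experiments are simulated.
- Problem sizes in tests and the acceptance script match the emulated
  experiments (3 replicates per condition, 8 stages, 4 masses) — the
  scale at which the assay is actually run.

## Known limitations

- The deletion-calibrated threshold depends on which deletion strains
  were assayed; with only three calibration genes it is a representative
  bound, not a per-probe specificity estimate.
- Pattern classification is a hard-threshold formalization of
  inherently qualitative vocabulary; genes near `T` or `F_min`
  boundaries can flip labels between replicate draws.
- Fold-changes of low-expressed genes are compressed by additive
  background (the ratio of background-inclusive means underestimates
  the specific-signal ratio); the package reports the measured ratio
  and attaches `T` to profiles so users can judge proximity to
  background.
- Concordance between platforms is a correlation of shapes after
  per-platform mean scaling; it cannot detect a shared multiplicative
  bias.
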