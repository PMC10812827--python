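# Methods

`oxwave` reimplements, as a tested pipeline over synthetic data with known
ground truth, the post-processing and statistical layers of an unbiased
PTM study of myocardial ischemia/reperfusion (I/R): open-search ΔM
analysis, differential-alkylation redox readout, hierarchical standardized
quantification, functional-category statistics, and oxidation-wave
time-course analysis. This note documents the models, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices made where the design was open.

## The synthetic experiment

The generator (`oxwave.simulate`) produces the study conditions the
analysis assumes:

- **Design.** A baseline group plus 7 reperfusion time points (20 min,
  40 min, 80 min, 2 h, 6 h, 12 h, 24 h), n = 4 biological replicates per
  group. TMT 10-plex layout: one plex per replicate, channel 1 a
  pooled-baseline reference, channels 2–9 carrying replicate r of every
  group. The layout is an explicit design table, so other mixing schemes
  are expressible without code changes.
- **Reporter model.** Lognormal multiplicative reporter noise (Gaussian in
  log2, σ = 0.18 per channel) with additional independent Gaussian log2
  effects at the peptide (σ = 0.10) and protein (σ = 0.10) levels — the
  simplest hierarchy consistent with the weighted spectrum–peptide–protein
  (WSPP) model's log-space variance assumptions. Each spectrum quantifies
  all ten channels; its reference-channel noise is shared by every ratio
  from that spectrum, as in real isobaric data.
- **Mass model.** Observed precursor masses carry Gaussian ppm error
  (σ = 1.5 ppm) plus an optional constant miscalibration offset
  (+8 ppm in the recalibration studies).
- **Injected biology.** Wave templates are stated in Zp units and
  converted to log2 deviations through the peptide-level SD implied by the
  noise model, so a template value of ~2.5 is expected back as Zp ≈ 2.5.
  Wave 1 (mono-oxidized Lys/Phe/Asn/Asp) peaks at 20 min and decays;
  wave 2 (mono/di/tri-oxidized Cys/Trp) and the reversible Cys-oxidation
  wave peak mid-course (6 h bump). Protein-abundance effects are organized
  by functional category: an "immune" category up +0.5 log2 from 2 h on,
  a "mitochondrial" category down −0.5 at 24 h. Default effect sizes are
  moderate on purpose: large enough that the pipeline should recover them,
  small enough that failure modes are visible.
- **Redox truth.** A fraction of Cys peptides get a time-varying
  reversibly oxidized fraction f_t = clip(f₀·2^(template·σ_Zp), 0.02, 0.9)
  with f₀ = 0.2. The methylthio-tagged form's abundance is proportional to
  f_t and the carbamidomethyl (reduced) form's to 1 − f_t, so total
  peptide abundance is conserved and the two forms' Zp series are
  anticorrelated. Because quantification is TMT-style (one PSM quantifies
  all samples), the redox state is encoded in the relative reporter
  intensities of the two peptidoforms, not in per-sample PSM counts.
- **Nuisance structure.** Decoy PSMs (reversed peptides, decoy
  accessions) with uniform ΔM, and an equal number of *false-target* PSMs
  drawn from the same shifted-down score distribution — without them an
  empirical false-target rate would be unmeasurable. Artifact ΔM
  populations (±1/±2 isotope-error spacings, an oxidation+carbamidomethyl
  combination) give the curation filter something to discard. A small
  per-PSM site-mislocalization rate (2%) and a per-plex peptide detection
  probability (0.95) create the replicate missingness the curation rule
  acts on.

**What the simulator does not emulate:** fragment spectra (PSMs are
sampled directly, not searched), chromatographic or batch drift beyond the
plex structure, isotope-impurity crosstalk between reporter channels,
score distributions with mass- or length-dependence, shared peptides
between proteins, and non-Gaussian heavy-tailed reporter noise. Passing
tests therefore demonstrate that the statistical machinery is correct and
calibrated under its own assumptions, not that those assumptions hold for
any particular instrument.

## Open-search ΔM post-processing

- **Recalibration** fits a single constant-ppm offset — the median signed
  ppm residual against the nearest integer-ΔM hypothesis, over a quality
  subset (score ≥ 0.15, |residual| ≤ 20 ppm, targets only) — and divides
  it out of every observed mass. A constant offset is the minimal model
  and matches what the generator injects. Peptides carrying real
  modifications a few mDa away from an integer (e.g. oxidation at
  +15.9949) enter the subset with a small bias; with the default modified
  fraction the median is robust to it and the residual systematic error
  stays well under 1 ppm. The correction is idempotent to numerical
  tolerance.
- **Histogram and peaks.** ΔM values are binned into half-open 1-mDa bins.
  Peak detection finds local maxima by frequency and slope on a 5-bin
  moving-average smoothing of the histogram (raw 1-mDa bins at realistic
  mass error, σ ≈ 2–4 mDa, are ragged enough that one population would
  fragment into satellites). Extents grow outward while smoothed counts
  decrease, adjacent candidates separated by a valley shallower than 50%
  of the smaller apex are merged, and a candidate survives only if its
  extent's raw count in excess of the local background (median
  occupied-bin count; zero when fewer than 100 bins are occupied) clears
  `min_count` — the support threshold is per population, since mass error
  spreads one population over many bins. The reported apex is
  the raw-count-weighted centroid. `min_count` defaults to
  max(10, 5 × median occupied-bin count); the floor exists because on a
  sparse uniform background the median occupied count is 1 and a pure
  multiple-of-median rule fires on Poisson noise, while on a noise-free
  histogram the occupied bins *are* the peaks, so when fewer than 100 bins
  are occupied the floor is used directly. All thresholds are exposed.
- **FDR** is plain target-decoy counting — PSMs sorted by descending
  score (decoys first at ties, the conservative order), FDR at rank k =
  decoys/targets, monotonized into q-values — at three scopes: global,
  local (half-open 1-Da bins [n−0.5, n+0.5)), and per assigned peak. The
  identification filter keeps targets at q ≤ 0.01.
- **Annotation** matches peak apexes against a curated known-shift TSV
  (Unimod-style monoisotopic masses computed from elemental formulas)
  within 10 mDa, ties broken by closeness then name. Artifact and
  known-combination entries are flags in the data, not code.
- **Truncation** explains a negative ΔM as the loss of up to 3 contiguous
  terminal residues (both termini, fewer residues preferred, N-terminus on
  ties). Gains are not enumerated: without the protein context the
  candidate set is unbounded, and the check exists to explain ΔM values of
  matched sequences.
- **Curation** keeps a (peptide, PTM, site) form iff its peak annotation
  exists and is neither artifact nor combination, the localized residue is
  allowed for that PTM (termini encoded as positions 0 and length+1), and
  the form was detected in ≥ 4 biological replicates of at least one
  group. Detection is per sample: a PSM covers every sample of its plex
  with positive reporter intensity. Under the default detection
  probability this rule removes roughly a quarter of true forms — the
  deliberate price of replicate-level reproducibility, mirroring the
  drastic curation funnel of real open-search studies.

## Hierarchical standardized quantification (Zp, Zq)

Spectrum-level log2 ratios (sample/reference channel; the reference is the
pooled baseline, so ratios are with respect to baseline by construction)
are integrated upward by inverse-variance weighting: spectra → peptidoform
per sample → protein per sample → per-sample grand mean. A child's weight
is w = 1/(σ²_level + 1/W_below), where W_below is its own integrated
precision. Each level's variance σ² is the fixed point at which the
standardized deviations z have unit variance, solved by bisection
(Brent) on σ² ∈ [0, ∞), floored at zero.

Three numerical choices matter:

- **Membership-corrected standardization.** For a child inside its
  parent's weighted mean, Var(x − x̂) = 1/w − 1/W; for a child standardized
  against an independently frozen parent it is 1/w + 1/W. Reported Zp and
  Zq use these exact denominators, which is what makes their null variance
  1 regardless of family size (the uncorrected (x − x̂)√w has variance
  1 − w/W, noticeably below 1 for proteins with few peptides). The
  uncorrected form remains available as the elementary `integrate_level`
  contract.
- **Winsorized fixed point.** The variance match uses 1–99% winsorized z
  and targets the winsorized variance of a standard normal (≈ 0.9637)
  rather than 1, so the robustification does not inflate σ². Only parents
  with ≥ 2 children inform the estimate.
- **Missing data.** A peptide's sample value uses only spectra observed in
  that sample; no imputation. Spectra with non-positive reference
  intensity are dropped with a warning.

**Two passes.** Level variances and protein values are estimated from
non-modified peptides only. Modified peptidoforms (the curated list) are
then quantified against those frozen anchors; the protein table is
produced in pass 1 and never touched, so adding modified peptides leaves
every Zq bit-identical — an invariant the tests check literally. Modified
forms of proteins with no non-modified peptide are flagged and excluded.

## Categories (Zc)

Zc = Σ member Zq / √n per sample — the minimal statistic that is standard
normal when member Zq are independent N(0,1) — with two-sided normal
p-values and Benjamini–Hochberg correction per time point (the
across-categories-only alternative is a flag). Size bounds default to
[5, 500]. Because Zq is referenced to the per-sample grand mean, a large
injected shift in one category drags the grand mean and pushes every other
protein slightly the opposite way; with the demo's 150-protein proteome
this compositional effect is visible in filler categories, while at a
realistic proteome size (thousands of proteins) it is negligible. The full
category-level variance estimation of the triangle model is expressible
through the same `integrate_level`/`estimate_level_variance` machinery;
sum/√n is the documented default.

## Redox classification

The differential-alkylation chemistry (free thiols blocked with
iodoacetamide during extraction → carbamidomethyl, +57.021464 Da;
reversibly oxidized Cys reduced on-filter and tagged with MMTS →
methylthio, +45.987721 Da) is interpreted per Cys site: the localized tag
mass within 10 mDa of either tag decides the state; no match, or a
multi-Cys peptide without per-site masses, is indeterminate. Tag masses
live in the modification list so other alkylator pairs are supported.
Under the fixed-carbamidomethyl search convention the methylthio form
appears as a ΔM ≈ −11.0337 peak, which is annotated and quantified like
any other modified form; its replicate-averaged Zp series is the
reversible-oxidation time course.

## Wave analysis

Replicate-averaged Zp matrices (rows = curated irreversible peptidoforms,
columns = time points in design order, per-cell n recorded) are clustered
by hierarchical agglomeration on the Pearson distance d = 1 − r; linkage
defaults to average (the distance, not the linkage, is prescribed by the
workflow this reimplements) and k = 2 mirrors the two-wave structure, with
constant rows dropped. Wave extraction filters a cluster's rows by
max-over-time Zp > 0 (or > 0.5 on averaged series); PCA is a
column-centered SVD with the largest-|loading|-positive sign convention.
Enrichment is hypergeometric on PSM counts (not peptide counts) per
(PTM type, residue), reported only above 50 population PSMs; per-protein
oxidized-PSM enrichment uses the total PSM population with BH correction.
Group differences use Mann–Whitney (exact two-sided for ≤ 10 per group)
and Kruskal–Wallis with tie correction; for a pooled n ≤ 8 the KW p-value
is an exact enumeration over all distinct assignments of the pooled values
to the group sizes, since the chi-square approximation is meaningless
there.

## Problem sizes and reproducibility

The recovery studies behind `scripts/acceptance.py` and the statistical
test suite use 20-seed batches of simulations with 120–220 proteins and
8–10 peptides per protein (≈ 10,000–28,000 PSMs per run, ≥ 500 proteins
for the null-calibration study) — sizes chosen so each study completes in
seconds to a couple of minutes while leaving the binomial margins of the
pass criteria intact. Every stage is deterministic given the seed; the
pipeline fans a single global seed out to per-stage seeds through named
`SeedSequence` keys, and re-running a config reproduces every stage table
bit-identically.

## Known limitations

- The spectral search itself (and its score) is out of scope; the score
  column is taken as given ("corrected XCorr" semantics are external).
- Protein inference is the PSM table's assignment; no protein-level FDR.
- The recalibration model is a single constant ppm offset, not a
  mass-dependent spline.
- Positive ΔM truncation "gains" are not explained.
- Multi-Cys peptides with mixed redox states are classified only when
  per-site tag masses are available.
- The compositional grand-mean effect on Zc (above) is inherent to
  grand-mean referencing at small proteome sizes.
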