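# Methods

## Acquisition design

The stepped-MRM design enumerates integer precursor masses from
`start_mz` (default 225) over `n_injections` (6) contiguous windows of
`window_width` (50) Da, each paired with its product at
`precursor − neutral_loss` (116 Da, the 2′-deoxyribose neutral). The
default design therefore spans 225→109 through 524→408 — exactly
6 × 50 = 300 transitions. Canonical-nucleoside transitions (precursors
228, 243, 252, 268) are generated and *flagged* rather than deleted, so
the total count is preserved while downstream stages can ignore them.
All discovery masses are unit-resolution integers, as appropriate for a
triple quadrupole; exact satellite offsets (Na⁺−H = +21.9819,
K⁺−H = +37.9559 Da) are kept in the offset constants and rounded to
+22/+38 for unit-mass matching.

## Standards library

The built-in library holds 23 damage products and epigenetic marks plus
the four canonicals, each obeying the −116 relation, with retention
times for the species validated by standard injection (N²-CMdG
3.45 min, 5-HMdC 2.72, 1,N⁶-ϵdA 2.93, 8-Oxo-dG 6.65). Isobaric species
legitimately share transitions (7-deaza-dX / 8-Oxo-dA / dG at 268→152),
so transition lookup returns all matches. 8-Oxo-dG carries a second
product ion (284→170) used by its targeted assay, stored as
`alt_product_mz` with 284→168 the default for discovery matching. The
artifact blacklist ships one entry: the protonated dC dimer (455→339)
at the dC retention time, an ionization artifact rather than a DNA
lesion.

## Synthetic data

The generator separates *biology* from *sampling*. A `panel_seed`
(default 2024) draws the species panel — unnamed adduct precursors,
retention times (uniform 1.5–16 min, the post-diversion elution
window), base abundances (lognormal, median 20 normalized units) and
per-tissue biases — while the per-cohort `seed` draws sample-level
noise and UV variability. Two cohorts simulated with different seeds
therefore measure the same underlying species, as two independent
studies of the same organism would; this is what makes cohort sharing
(curation rule vii, merge statistics) meaningful.

Per-sample abundance is multiplicative:
`base × tissue × age × sex × lognormal(CV)` with mean-one lognormal
noise at CV 0.22 by default (the reproducibility level reported for
signals detected across all samples). Age effects are geometric
interpolations of a configured fold change across the age span (the
validated defaults: 5-HMdC 2.8×/1.7×/1.4× in liver/kidney/brain,
N²-CMdG 3×/1.5× in liver/heart, 8-Oxo-dG 1.8× in liver, all over 1→26
months); sex ratios apply √ratio to females and 1/√ratio to males
(defaults: 1.5 F/M for 5-HMdC in heart and kidney and 5-FdC in
kidney). 5-MdC is planted at 5×10⁴ normalized units — orders of
magnitude above every adduct, matching its status as ~1% of genomic
dC. Satellites are deterministic fractions of their parent (M+1 0.15,
M+2 0.02, Na 0.05, K 0.02 — plausible values for small nucleosides,
chosen to exercise the filters, not claims about any instrument) and
share the parent's retention time and peak width. Unnamed precursors
are kept clear of every satellite position of every planted species
while the mass range allows (a few dozen species); denser panels fall
back to uniqueness only.

Chromatogram rendering is a separate step: Gaussian peaks (σ drawn
0.05–0.11 min per species) on a 0–24 min grid at 0.02 min steps, with
raw area reconstructed as `abundance × UVsum / scale` so UV
normalization recovers the truth, plus optional Gaussian baseline
noise (0.5 counts default). Blank and no-nuclease control channels
carry baseline noise only and no canonical UV signal — intact DNA
yields no free nucleosides at the detector. UV canonical areas follow
genome composition (21% dG/dC arms, 29% dA/dT) times injected DNA
mass, so the normalization denominator scales with DNA load.

What the generator does *not* emulate: ion suppression and matrix
effects, retention-time drift between runs, peak tailing, detector
saturation, and correlated (non-lognormal) biological covariation.
Passing tests therefore demonstrate that the pipeline's logic is
correct under its stated statistical model, not that it is robust to
every instrumental pathology of real LC–MS data.

## Peak processing

The detector is a plain apex-over-SNR detector: local maxima above
`min_snr` (5) times a robust noise floor (1.4826 × MAD), with a
prominence requirement at the same level, minimum FWHM 0.05 min,
trapezoid integration over ±3σ around the apex (σ from the measured
half-width), and valley splitting between overlapping peaks. It is
deliberately simple — adequate for Gaussian synthetic peaks — because
the reference workflow used vendor software whose algorithm is
unspecified; every setting is explicit configuration. Each peak keeps
an 11-point apex-centered profile for shape correlation; the window is
kept narrow (±0.1 min) so a small peak's profile is not swamped by the
tail of a large neighbour a few σ away.

Normalization: `intensity = scale × area / Σ(UV canonical areas)` with
a single global `scale` (default 1000) placing typical adducts in the
1–10³ range where the 2.0 intensity threshold is meaningful (the raw
units are instrument-dependent). Blank/control injections have no
canonical UV signal, so the pipeline normalizes them by the mean
hydrolysate UV sum to keep control intensities comparable during
curation; without a fallback the operation errors, naming the sample.
Cross-sample alignment groups signals on a transition by
single-linkage in retention time with a 0.2 min gap tolerance,
keeping the strongest peak per sample per group.

## Curation

Rules run in the order i → iii → ii → iv → v → vi → vii: the
structural fragment rule first, control/blank presence before
intensity comparisons, then satellites, blacklist, and the intensity
floor. The ordering matters and is fixed: the satellite rules (iv, v)
take their candidate parents from the survivors of rules i + iii + ii
only, so a contaminant cannot shield a satellite. Each removed signal
records its first failing rule.

Choices where the rule statements leave room:

- "Average background" is the per-transition mean over blank
  injections, floored at 0.05 normalized units when blanks are clean.
- "Present in a control" is an absolute threshold (0.5 normalized
  units): a detected baseline blip in a blank sits far below it, a
  contaminant far above. Deriving the threshold from blank statistics
  would be circular when the blanks are themselves contaminated.
- "Detected in all individual samples" is evaluated per tissue: a
  signal passes rule ii if *some* tissue has both mean intensity ≥ 3×
  background and detection in every sample of that tissue.
- Isotopomer removal (rule v) requires the +1/+2 precursor offset,
  retention-time coincidence, minority intensity (fraction < 0.5 — a
  true M+1 of a small nucleoside cannot exceed ~25%, so 0.5 is
  deliberately permissive) and, where shape profiles exist, Pearson
  shape correlation ≥ 0.9. With noisy data the shape test can fail for
  very small M+2 peaks, which then survive — a conservative outcome
  (a possible satellite retained rather than a possible adduct
  removed) that mirrors the residual isotopomer fraction any real
  curation tolerates.
- Rule vii's "shared between cohorts" is evaluated against the other
  cohort's pre-rule-vii survivors, so a weak signal is rescued by a
  cohort in which it was not weak.

`merge_cohorts` unions basis sets keyed by transition plus nearest
retention time within tolerance, so |union| = |set1| + |set2| −
|shared| holds identically. `tissue_sets` enumerates all 2⁴−1 Venn
regions for four tissues from per-tissue mean intensities against a
detection threshold.

## Quantification

Calibration is a through-origin least-squares slope (`Σxy/Σx²`) of
std/IS area ratios versus concentration — through the origin because
the assay reports a slope-only response factor; an affine fit is
available by flag. R² is computed against the fitted model (uncentered
for the through-origin case). Quantification inverts the ratio model;
a zero internal-standard area is an error (IS failure), not a zero.
The lesions-per-10⁹-nt conversion is `amount_fmol × 10⁻¹⁵ /
nt_total_mol × 10⁹`; `nt_total` is an explicit, UV-quantified input
rather than a constant derived from nominal DNA mass, because the two
differ in practice (the published conversion pairs imply ≈1.82×10⁻⁸
mol per injection, whereas 10 μg of DNA at ~330 g/mol per nucleotide
would give ≈3×10⁻⁸). LOQ estimation takes the lowest calibration level
with mean signal ≥ 10× blank noise and replicate CV ≤ 20%; both
thresholds are configuration, since published LOQs of this kind are
rough operating bounds rather than the output of a statistical
detection-limit model.

## Statistics

Adduct load sums per-tissue mean normalized intensities over all
species except 5-MdC (whose epigenetic signal would swamp the damage
load). Integer percentages use largest-remainder (Hamilton)
apportionment: floor each share and distribute the leftover points to
the largest fractional remainders. This guarantees a 100 total and
matches how published percentage sets of this kind are rounded.

Sex comparisons are two-sided Mann–Whitney U tests (exact for small
untied samples, normal approximation otherwise; a species constant
across all samples reports p = 1). FDR uses Storey q-values: π₀
estimated on the λ grid 0.05…0.95 via #{p > λ}/(m(1−λ)), smoothed with
a cubic polynomial evaluated at λ = 0.95, clipped to (1/m, 1]; inputs
with m < 30 fall back to the conservative π₀ = 1, where the procedure
reduces exactly to Benjamini–Hochberg. Age trends are per-species
one-way ANOVA across age groups with Bonferroni-adjusted pairwise
t-tests and an oldest/youngest fold change; human age association uses
Pearson correlation with its two-sided t-test.

Clustering log₁₀-transforms intensities (pseudocount = half the
smallest nonzero value — the generative model is lognormal, and the
transform is exposed as configuration since the reference workflow
does not state its own), autoscales per species, and projects samples
onto the smallest number of principal components reaching 80%
cumulative variance (configurable; comparable analyses used 4–6
components at ~82–83%). Gaussian mixtures with 1–9 components are
fitted for four covariance parameterizations (per-component spherical,
diagonal, one shared full matrix, per-component full — the constraint
families of the mclust-style workflow as available in scikit-learn,
which has no equal-volume spherical family), and the model maximizing
BIC is selected, with BIC reported in the larger-is-better sign
convention. Two numerical safeguards prevent a known EM pathology in
which a component shrink-wraps a few chance-close points and its
likelihood diverges, letting BIC favor arbitrarily many clusters:
component covariances are floored at 1% of the score variance, and
each fit uses a single k-means-initialized EM run rather than many
random restarts.

## Problem sizes and determinism

The demo pipeline and test suite run on reduced configurations (2–4
tissues, 2 ages, 2–4 animals per cell, 6–10 unnamed species) chosen so
the full chain — render, detect, normalize, curate, merge, annotate,
statistics — executes in seconds while still containing every signal
class the filters must handle. Property suites use 20 seeds; the null
calibration uses 100 species × 20 seeds (2000 species-tests). All
randomness flows through explicit seeds (`panel_seed` for biology,
`seed` for sampling, the clustering seed for EM initialization), and a
run's outputs are byte-identical given the same configuration and
seed.

## Known limitations

- The curation tree's satellite rules operate on aligned consensus
  signals, not raw traces; heavily overlapping species on one
  transition are integrated as one signal.
- The shape-correlation test needs rendered peak profiles; curation of
  pre-integrated tables falls back to RT/intensity criteria alone.
- The peak detector assumes near-Gaussian peaks on a uniform time
  grid; it is not a general chromatographic deconvolution.
- Storey's π₀ smoother is a cubic-polynomial fit rather than the
  spline of the original R implementation; for π₀ near 1 and m in the
  hundreds the difference is well below the procedure's own Monte
  Carlo variability.
- The GMM candidate set omits an equal-volume spherical family; count
  selection on separated clusters is insensitive to this.
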