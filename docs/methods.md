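# Methods

## Problem and model

Tau-PET uptake (SUVR, [¹⁸F]AV-1451) in lateral occipital association cortex
is markedly higher in posterior cortical atrophy (PCA) than in dementia with
Lewy bodies (DLB), even though the *pattern* of occipital binding overlaps.
`tauroc` implements the quantification and statistics that turn that contrast
into a classifier: regional SUVR extraction, data-driven derivation of an
occipital composite region by AUC ranking, and ROC discrimination of the
composite against global amyloid (PiB) burden.

## Voxel quantification

**Two-compartment partial-volume correction.** Each PET voxel mixes signal
from brain tissue and (signal-free) CSF.  With gray/white/CSF fractions per
voxel, the corrected value is `pet / (GM+WM)`.  Voxels with
`GM+WM < min_tissue` (default **0.2**) are excluded — marked invalid, never
clamped — because the division amplifies noise without bound as the tissue
fraction goes to zero.  The floor's value is a convention, not an estimate;
the corrected/uncorrected comparison is a first-class pipeline flag.
Correction precedes normalization and covers the reference region
identically, so the two operations commute on tissue-homogeneous volumes.

**SUVR normalization.** All valid voxels are divided by the **median** of the
pooled bilateral cerebellar-crus voxels; the reference-region median of the
output is 1 by construction, and all SUVR outputs are invariant under
rescaling of the input activity.

**Regional aggregation.** The median of valid voxels per atlas label.  The
median is prescribed for the reference region and the composite score; we
apply it uniformly to single regions as well (the statistic for single
regions is otherwise unspecified), for internal consistency and robustness
to the heavy-tailed uptake distributions of patient scans.  Regions with no
valid voxels propagate as missing values, never zero.  The global amyloid
meta-ROI is the median over the *pooled* voxels of all member labels
(bilateral parietal incl. posterior cingulate/precuneus, orbitofrontal,
prefrontal, temporal, anterior cingulate), not a mean of regional medians.

**Voxel-wise maps.** Two-sample pooled-variance t per voxel (df = n₁+n₂−2,
no covariates), two-sided p; zero-variance voxels get t=0, p=1 rather than
±∞.  Suprathreshold voxels (p < 0.001 by default) are grouped under
**18-connectivity** (faces + edges; 6/26 selectable) and components must
*strictly exceed* the extent threshold (default 25 voxels: a 25-voxel
cluster is discarded, 26 survives).  These conventions follow the
statistical-mapping software family the analysis standardizes on.

## Composite derivation

**Asymmetry screen.** Left−right differences per region and group, tested by
Wilcoxon signed-rank (chosen over a paired t-test because group sizes of
18–33 do not support normality assumptions); a group×region is flagged when
the Bonferroni-corrected p (multiplier = regions × groups screened) falls
below 0.001.  A clean screen ("no asymmetry detected") licenses combining
hemispheres; combination is the arithmetic mean of left and right (max is
available for sensitivity analysis).

**AUC ranking.** Per combined region, AUC = U/(n_pos·n_neg) with ties
counted ½, oriented so PCA-higher gives AUC > 0.5.  P-values come from the
Mann–Whitney test: exact enumeration when n_pos·n_neg ≤ 400 and there are no
ties, otherwise the normal approximation with continuity and tie correction.
Bonferroni multiplies by the number of regions actually tested (46 with the
default atlas; recomputed when regions are excluded for missing data).
Ties in AUC break by region name so rankings are reproducible.

**Selection and scoring.** Regions with AUC **>** threshold (default 0.97 —
deliberately an explicit, arbitrary cutoff that the CLI refuses to default)
and corrected p **<** 0.001, both strict, form the composite; the
per-subject score is the median SUVR over members.  Selection is in-sample;
the optimism of selecting and evaluating on the same cohort is a documented
property of the original design, not corrected here.

## Discrimination

Empirical ROC over all distinct observed scores (plus a +∞ sentinel);
positive call when **score ≥ threshold** — ties are called positive, which
matters at the full-specificity point.  Trapezoidal AUC equals the
Mann–Whitney estimate on finite samples (property-tested against exhaustive
pair counting).  Operating points: *full specificity* (max sensitivity among
thresholds with specificity 1) and *Youden* (max sens+spec−1, ties toward
higher specificity).  The binormal closed form Φ(Δμ/√(σ₁²+σ₂²)) serves as an
analytic oracle for published group summaries.  Marker comparison uses a
paired subject-level bootstrap (2,000 reps, seeded) percentile interval for
the AUC difference, plus best specificity at fixed sensitivity levels
(0.7/0.8/0.9/1.0).

**Operating-point ambiguity.** The published headline is 88 % sensitivity at
100 % specificity, i.e. 16/18.  With the printed extremes — DLB maximum 1.42,
PCA second-lowest 1.45 — a strict full-specificity threshold sits in
(1.42, 1.45] and yields 17/18.  The default synthetic preset therefore pins
the second low-uptake PCA subject *at* the DLB ceiling (1.42 instead of
1.45), reproducing 16/18 deterministically; the discrepancy is stated in the
discrimination report (`operating_point_note`) rather than hidden, and a
`printed_extremes=True` preset realizes the strict 17/18 reading.

## Synthetic data: what it emulates, and what it does not

**Cohort generator.** Group scores are truncated normals (rejection
sampling) inside the published ranges; tau and amyloid scores correlate
through a shared Gaussian factor (default ρ = 0.5 — the source reports
concordance of the low/low subjects but no coefficient).  The PCA group is a
mixture: 2 of 18 subjects form a low-uptake subcomponent, concordant across
tracers, defaulting to pinned values (tau 1.31/1.42, amyloid 1.51/1.56) with
a uniform-bridge option on the printed window.  Because the published group
moments include those subjects, the preset places the bulk component at
`(n·mean − Σ pinned)/(n − k)` so the *mixture* mean reproduces the published
group mean; no additional re-adjustment is made for truncation shrinkage
(the printed ranges are ≳2.5 SD wide, shrinking means by < 0.01 SUVR).  The
bulk PCA component is truncated to [1.45, 3.77] — above the printed
second-lowest value — so the group range decomposes cleanly into outlier
band plus bulk.  The two published DLB extreme subjects (tau 1.02/1.42 with
amyloid 1.45/1.46) are anchored as realized values, so the empirical DLB
ceiling exists in every simulated cohort.  Unpublished amyloid ranges
default to mean ± 3 SD (the PCA bulk floored just above its outlier band).
One RNG stream per group (seed ⊕ CRC32 of the group name) keeps groups'
draws independent of cohort composition.

An alternative preset (`figure2_cohort_spec`) uses the box-plot summary of
the composite (PCA 2.75 ± 0.68, DLB 1.18 ± 0.10), which differs from the
main-table values without explanation in the source; the main-table preset
is the default.

**Regional profiles.** The three occipital regions are built from a latent
per-subject composite (the cohort generator's draw) plus fixed offsets
(−0.04/0/+0.04) and 0.02-SD noise, so the trio median recovers the latent
score.  Other regions follow `group base + separation·1[PCA] + subject
effect (SD 0.05) + noise` with separations tiered by anatomy: moderate
(0.22) in medial occipital and temporoparietal association cortex, small
(0.12) elsewhere in cortex, near-zero (0.04) in deep gray/limbic regions —
mirroring the reported widespread-but-occipital-dominant contrast while
keeping every non-occipital AUC safely below the 0.97 selection cutoff.
Left and right share region means (no built-in asymmetry).  Low-uptake PCA
subjects track the DLB level outside the occipital trio.

**Phantoms.** Axis-aligned cuboid regions on a 32³ grid with
`pet = uptake·(GM+WM) + N(0, σ)`; the quantification chain inverts this
exactly at σ = 0, which the tests assert to 1e-12 relative precision.

**What a green test does not establish.** The generator has no scanner
physics (PSF, scatter, motion), no registration error, no spatial
autocorrelation beyond block structure, no longitudinal change, and its
distributions are parametric stand-ins for 151 real scans.  Green tests
certify the *statistical machinery* — not clinical performance on real data.

## Numerical conventions

- Rejection sampling aborts with a diagnostic after 10,000 consecutive
  rejected draws (mis-specified truncation window).
- Determinism: every stochastic path is driven by `numpy` `SeedSequence`
  children of one seed; identical config+seed reproduces output files byte
  for byte.  For that reason output files carry a config hash and package
  version but no timestamps.
- Missing values are NaN end to end and serialize as empty CSV fields.
- AUCs print at 2 decimals in summaries; machine outputs keep full
  precision.

## Known limitations

- The 46-pair/122-label default atlas is a naming stand-in, not real
  anatomy; phantom geometry is cuboid.
- The asymmetry screen's Bonferroni multiplier (regions × groups) and the
  choice of Wilcoxon are conventions where the source names none.
- In-sample composite selection is optimistic by construction (see above).
- The uniform low-uptake bridge and the Gaussian copula are least-assumptive
  choices fit to two observed subjects; they are not identifiable from the
  published summaries.
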