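# tauroc

Tau-PET quantification and ROC analysis for separating **posterior cortical
atrophy (PCA)** from **dementia with Lewy bodies (DLB)**.

The two syndromes overlap clinically (visuospatial deficits, occipital
hypometabolism) and both occipital cortices bind the tau tracer
[¹⁸F]AV-1451 — but the *magnitude* of uptake differs sharply.  `tauroc`
implements the full analysis chain that exploits this:

1. **Voxel quantification** — two-compartment CSF partial-volume correction
   (`pet / (GM+WM)` per voxel, voxels below a tissue floor excluded),
   normalization to the median of the bilateral cerebellar-crus reference
   (SUVR), atlas-based regional medians, a pooled global amyloid meta-ROI,
   and voxel-wise pooled-variance t-maps with cluster-extent thresholding
   (default *P* < 0.001, extent > 25, 18-connectivity).
2. **Composite derivation** — left/right asymmetry screening (Wilcoxon
   signed-rank), hemisphere combination, per-region AUC ranking
   (AUC = U/(n₁n₂), Mann–Whitney p, Bonferroni-corrected), and selection of
   regions with AUC > 0.97 at corrected *p* < 0.001 into an **occipital
   composite** (superior + middle + inferior occipital cortex) scored as the
   per-subject median SUVR.
3. **Discrimination** — empirical ROC curves (positive call: score ≥
   threshold), full-specificity and Youden operating points, the closed-form
   binormal oracle AUC = Φ(Δμ/√(σ₁²+σ₂²)), and a paired-bootstrap
   head-to-head comparison of the tau composite against global PiB SUVR.
4. **Synthetic data** — because the underlying clinical cohort is not
   public, a first-class generator reproduces its published statistical
   structure: truncated-normal group scores (CN n=100, DLB n=33, PCA n=18)
   with a two-subject low-uptake PCA mixture, correlated tau/amyloid scores,
   per-region gradients for ranking, and 3-D cuboid phantoms with known
   uptake and tissue fractions for exact pipeline inversion tests.

## Worked example

```python
import tauroc as tr
from tauroc.synthetic import AV1451_COMPOSITE, PIB_GLOBAL

spec = tr.table1_cohort_spec()            # published group parameters
cohort = tr.generate_cohort(spec, seed=1)
sub = cohort[cohort["group"].isin(["DLB", "PCA"])]

roc = tr.roc_curve(sub[AV1451_COMPOSITE], sub["group"], positive="PCA")
op = tr.operating_point(roc, "full_specificity")
print(f"composite AUC: {roc.auc:.2f}")
print(f"full-specificity: sens {op.sensitivity:.1%}, spec {op.specificity:.1%}")
print(f"PiB AUC: {tr.roc_curve(sub[PIB_GLOBAL], sub['group']).auc:.2f}")
print(f"binormal oracle (PiB): {tr.binormal_auc(1.69, 0.45, 2.36, 0.39):.2f}")
```

prints

```
composite AUC: 0.99
full-specificity: sens 88.9%, spec 100.0%
PiB AUC: 0.89
binormal oracle (PiB): 0.87
```

The tau composite separates the simulated patient groups almost perfectly
(AUC 0.99); at a threshold leaving every DLB subject below it, 16 of 18 PCA
subjects are still called positive (88.9 % sensitivity at 100 % specificity —
only the two low-uptake PCA subjects are missed).  Global amyloid burden
discriminates far less cleanly (AUC ≈ 0.87–0.89), since many DLB patients
carry amyloid too.

The same analysis, end to end with files on disk:

```bash
tauroc run --seed 1 --outdir out/          # cohort → screen → rank → select → score → ROC
tauroc simulate phantom --outdir phantom/  # NIfTI phantom volumes + labels.json
tauroc quantify --pet phantom/pet.nii.gz --gm phantom/gm.nii.gz \
    --wm phantom/wm.nii.gz --atlas phantom/atlas.nii.gz \
    --labels phantom/labels.json --out regional.csv
```

## Acceptance script

`scripts/acceptance.py` regenerates the headline quantities from scratch by
running the generator and the AUC machinery (no stored results): the mean
empirical composite AUC over 1,000 simulated 33-vs-18 cohorts, and the DLB
and PCA composite group means averaged over 200 simulated cohorts each.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
assumptions and their limits, numerical conventions, and known ambiguities
(e.g. how the full-specificity sensitivity depends on tie handling).
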