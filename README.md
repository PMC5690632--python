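# meningrad

Radiographic prediction of meningioma WHO grade from contrast-enhanced
T1-weighted MRI: a reusable, tested implementation of the full analysis —
3D radiomic feature extraction inside a tumor segmentation, univariate
screening of semantic and radiomic features against grade, and
random-forest grade classification with temporal validation — together with
a synthetic phantom cohort generator so every stage runs and is validated
with no patient data.

**Who it is for.** Researchers in quantitative neuro-imaging who want a
transparent, oracle-tested reference for this class of radiomics analysis:
the texture matrices and filter banks are implemented from their
definitions and verified against naive enumeration, the statistics against
exact combinatorial oracles, and the whole pipeline against a generative
phantom model with calibrated effect sizes.

## The analysis

Meningiomas are graded histopathologically after resection (grade I = low;
II–III = high, ~41% of the modelled cohort). The question is how much of
that grade is already visible pre-operatively on MRI. Two feature streams
quantify the imaging phenotype of the contoured tumor:

* **10 semantic features** — binary traits scored by a radiologist
  (intratumoral heterogeneity, necrosis/hemorrhage, sinus invasion, mass
  effect, …). Screened against grade with the conditional-MLE odds ratio,
  Fisher's exact test, and exact CIs.
* **15 radiomic features** — computed descriptors drawn from a 1,055-name
  feature space (55 intensity/texture features per filter channel × 19
  channels + 10 shape features). Channels are the original volume, 8
  stationary-wavelet subbands (Coiflet-1, `LLL`…`HHH`), and 10
  Laplacian-of-Gaussian scales (σ = 0.5…5 mm). Texture features come from
  gray-level co-occurrence (GLCM), run-length (GLRLM), and size-zone
  (GLSZM) matrices on a 32-level discretization, e.g.

      HILAE = Σᵢⱼ i²j² S(i,j) / Nz

  (high-intensity large-area emphasis: large bright zones, e.g.
  hemorrhage), plus shape features such as spherical disproportion
  SD = A / 4πr², r = (3V/4π)^⅓. Screened with the Mann–Whitney AUC and
  Noether's test; all screens are Benjamini–Hochberg adjusted.

Classification uses six random forests over nested feature sets (clinical,
location, semantic, radiomic, radiographic = location+semantic+radiomic,
combined), trained on the temporally earliest 75% of patients with
training-only feature selection and inner-CV tuning, validated on the rest,
and compared pairwise by bootstrap.

## Worked example

```python
from meningrad import PhantomSpec, make_phantom, preprocess, extract_panel

# a large, irregular, heterogeneous phantom tumor with a necrotic core
img, mask = make_phantom(
    PhantomSpec(base_radius_mm=14, irregularity=0.2,
                heterogeneity=0.3, necrosis_fraction=0.25),
    seed=42,
)
pimg, pmask = preprocess(img, mask, spacing_mm=3.0)   # clip ±3 SD, resample
feats = extract_panel(pimg, pmask)                    # 15-feature panel
for name in ("Minimum", "Difference Entropy", "Spherical Disproportion",
             "Run Length Non-uniformity",
             "HHH High Intensity Large Area Emp.",
             "HLH Low Intensity Large Area Emp."):
    print(f"{name:40s} {feats[name]:10.4f}")
```

prints

```
Minimum                                     19.5822
Difference Entropy                           4.0114
Spherical Disproportion                      1.0798
Run Length Non-uniformity                  355.1597
HHH High Intensity Large Area Emp.        7803.3822
HLH Low Intensity Large Area Emp.            0.1172
```

The necrotic core pulls the intensity minimum far below the 100-unit base
signal and inflates the low-intensity large-area emphasis; the radial
perturbation lifts spherical disproportion above the ~1.06 of a digital
ball of this size; the heterogeneity field drives the entropy, run-length
and size-zone values.

The same flow from the shell, on a whole cohort:

```bash
meningrad simulate --outdir run/ --seed 1 --n-patients 175
meningrad extract  --outdir run/
meningrad analyze  --outdir run/ --seed 1
```

which writes the screen tables (`semantic_screen.csv`,
`radiomic_screen.csv`, 150-cell `association_map.csv`, atypia screens), the
six-model validation table (`model_results.csv`), pairwise bootstrap
comparisons, and a plain-text report, all under seeded, manifest-checksummed
reproducibility.

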