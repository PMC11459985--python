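# phantomrad

Stability analysis of PET radiomic texture features on a digital
heterogeneous phantom.

## The problem

Radiomic texture features extracted from PET images are candidate
imaging biomarkers, but their values shift when images are
reconstructed with different settings (OSEM subsets and iterations,
time-of-flight, Gaussian post-filter width). A feature is clinically
useful only if it is both **stable** against such reconstruction
changes and still **able to distinguish** genuinely different uptake
patterns — for example a homogeneous lesion from a heterogeneous one.

`phantomrad` studies this trade-off in a fully synthetic, fully
reproducible setting. It simulates a water-filled cylinder phantom
(5 kBq/ml background) holding four artificial tumour inserts, each
built from seven parallel syringes on a 38 mm pitch circle
(insert volume ≈ 145 cm³):

1. homogeneous — all 7 syringes at 40 kBq/ml;
2. homogeneous with necrotic core — 6 × 40 kBq/ml, one cold syringe;
3. heterogeneous — syringes mixing 20 / 40 / 80 kBq/ml (max:min = 4:1);
4. heterogeneous with necrotic core.

Reconstruction is emulated in image space: intrinsic Gaussian PSF
blur, zero-mean noise whose standard deviation scales with
√(iterations × subsets) and is divided by a TOF gain, then a Gaussian
post-filter at the setting's cut-off FWHM. Twenty-one settings are
generated by one-at-a-time variation around the clinical default
(24 subsets, 2 iterations, 6.4 mm filter, TOF on): subsets
∈ {12, 16, 18, 24, 32}, iterations ∈ {1..6}, filter ∈ {0..7} mm,
TOF ∈ {on, off}.

## The analysis

For every (shape, setting) pair a single fixed ROI — the 7-syringe
footprint — is overlaid on the image and **78 IBSI-style 3D texture
features** are computed from five matrix families (25 GLCM, 16 GLRLM,
16 GLSZM, 16 GLDZM, 5 NGTDM), after fixed-bin-number discretization
(Ng = 64) and using the merged 13-direction 3D aggregation.

Per feature, the coefficient of variation

COV = 100 · SD / mean  (%)

is computed within each setting family and categorized: stable
(COV ≤ 5 %), moderately stable (5–10 %], poorly stable (10–20 %],
unstable (> 20 %). Stable features are then tested with the Friedman
rank statistic on every pair of insert shapes across the n = 21
settings (k = 2 regions per pair):

Q = 12 / (n·k·(k+1)) · Σⱼ Rⱼ² − 3·n·(k+1)

with p from the χ²(k−1) tail (an exact permutation mode is available
for k = 2). A feature is **distinguishable** when p < 0.05 for all
C(4,2) = 6 shape pairs.

## Worked example

```bash
phantomrad run-all --seed 1 --outdir out/
```

prints (abridged):

```
phantomrad run (config 5f2d20f39331f118, seed 1)
  features extracted : 78
  recon settings     : 21
  insert shapes      : 4 (6 pairwise comparisons)
  stability categories (overall):
    stable             50
    moderately_stable  13
    poorly_stable      15
    unstable           0
    undefined          0
  stable features    : 50
  distinguishable    : 42
    - glcm_autocorrelation
    - glcm_cluster_shade
    ...
    - ngtdm_strength
```

Reading this: of the 78 features, 50 kept an overall COV ≤ 5 % across
all 21 reconstruction settings (averaged over the four setting
families and four shapes); of those, 42 separated every pair of insert
shapes with Friedman p < 0.05 and are therefore stable *and* sensitive
to uptake heterogeneity on this synthetic phantom. `out/` contains the
long-form feature table (`features.csv`), per-shape stability records
(`stability.csv`), per-pair Friedman results (`discrim.csv`) and a
JSON report with provenance (config hash, seed).

The same stages are available individually (`simulate`, `extract`,
`stability`, `discrim`), and the library API (`phantomrad.extract_all`)
accepts any NIfTI volume/mask pair via `phantomrad.io`.

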