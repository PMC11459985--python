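# Methods

## Phantom model

The phantom is a water cylinder (radius 100 mm, length 120 mm,
background 5 kBq/ml of F-18) holding four syringe-array tumour inserts
at 90° to each other, voxelized on an isotropic 2 mm grid by the
centre-point rule (a voxel belongs to a syringe iff its centre lies
inside; no partial-volume subsampling). Each insert is seven parallel
syringes: one on the insert axis and six on the 38 mm pitch circle.

Syringe dimensions are radius 9.5 mm × length 73 mm. These two numbers
are the package's own resolution of an under-determined geometry: only
the pitch-circle diameter (38 mm) and the total insert volume
(≈ 145 cm³) are fixed by the design. With six syringes on a 19 mm-radius
ring plus a central one, adjacent axes are 19 mm apart, so the largest
non-overlapping radius is 9.5 mm; the length is then set by the volume
target (7 · π · 9.5² · 73 mm³ = 144.9 cm³). Voxelized, the ROI measures
145.15 cm³ on the default grid.

The necrotic syringe is modelled as cold water at background activity;
the heterogeneous layout puts 40 kBq/ml (shape 3) or the cold syringe
(shape 4) at the centre with the ring alternating 80/20 kBq/ml. The
source design states neither the necrotic filling nor the spatial
assignment of activities, so both are fixed deterministic conventions
exposed through `InsertConfig` rather than inferences.

## Reconstruction surrogate

True sinogram-level OSEM/PSF/TOF reconstruction is out of scope; the
pipeline degrades images directly in image space with a model whose
shape follows the known physics of iterative PET reconstruction:

| parameter | default | meaning |
|---|---|---|
| `psf_fwhm` | 5 mm | intrinsic scanner resolution (Gaussian blur before noise) |
| `base_noise_sd` | 0.5 kBq/ml | noise SD at the reference product (10 % of background) |
| `reference_product` | 48 | iterations × subsets of the clinical default (2 × 24) |
| `tof_gain` | 1.35 | factor dividing the noise SD when TOF is on |

Noise SD = `base_noise_sd · sqrt(iterations·subsets / 48) / tof_gain^[tof]`;
the rationale is that each OSEM update adds noise roughly in proportion
to the square root of the accumulated update count, and TOF improves
the effective SNR by a constant factor. The post-filter is a Gaussian
at the setting's cut-off FWHM (0 mm = none), applied after the noise so
it smooths signal and noise alike; negative voxels are clipped. All
constants are configuration parameters, not hard-coded.

Settings with identical physical parameters (the subsets=24,
iterations=2 and TOF=on variations all coincide with the default)
receive the same derived noise seed and therefore the identical image,
mirroring a study in which all settings are reconstructions of one
acquisition.

## Feature extraction

78 features from five 3D texture families (25 GLCM, 16 GLRLM,
16 GLSZM, 16 GLDZM, 5 NGTDM), evaluated per the IBSI formulations.
Dialect choices, each config-exposed:

- **Discretization**: fixed bin number, Ng = 64, over the in-ROI
  min–max range. This makes every feature invariant to positive affine
  intensity rescaling (property-tested).
- **Aggregation**: one matrix merged over the 13 unique 3D directions
  at distance 1 (GLCM/GLRLM); zones use 26-connectivity; NGTDM uses the
  Chebyshev 26-neighbourhood.
- **GLDZM distance**: city-block distance to the first voxel outside
  the ROI, minimum 1; the image border counts as outside.
- **Degenerate conventions**: a constant ROI yields a single-cell
  GLCM (joint maximum 1, contrast 0); GLCM correlation is 1 when the
  marginal variance vanishes; information correlation 1 is 0 when the
  marginal entropy vanishes; NGTDM coarseness is capped at 1e6 and
  busyness/strength/complexity/contrast are 0 when their denominators
  vanish.
- **Resampling**: trilinear to 2 mm isotropic for the volume, nearest
  neighbour for the mask (only triggered for user-supplied volumes;
  phantom grids are already isotropic 2 mm).

Every matrix builder is verified against independent brute-force
enumeration oracles (pair loops, run walks, BFS flood fill, Manhattan
distance scans, neighbour loops) on random small ROIs.

## Stability

COV = 100 · sample SD (n−1) / |mean|, computed per setting family
(5 subsets / 6 iterations / 8 filter / 2 TOF settings; the default's
image participates in every family whose variation list contains its
value). The overall score defaults to the arithmetic mean of the four
family COVs; a pooled COV over all 21 settings is available
(`--overall-cov pooled`) because "average over all tested settings" is
ambiguous between the two readings. A mean within 1e-12 (relative to
the value scale) of zero flags the COV undefined; such features are
excluded from categorization and reported separately. Category
boundaries are inclusive on the stable side: COV = 5 % is stable.

The pipeline computes stability per insert shape; the overall stable
set used for the Friedman stage categorizes the mean of the four
per-shape overall COVs, since the categorization region is not
otherwise determined. The per-family category histogram in the run
report is taken from shape 1 (the homogeneous reference whose contour
defines the ROI).

## Discriminability

Friedman test per feature and shape pair: rows are the 21 settings,
columns the two regions; midranks break ties; Q = 12/(n·k·(k+1))·ΣRⱼ²
− 3n(k+1); p from the χ²(k−1) upper tail. Because the χ² approximation
is weak at k = 2, an exact permutation mode enumerates the
Binomial(m, ½) null over the untied rows (n ≤ 25) — both modes are
reported options; χ² is the default. No multiple-testing correction is
applied: the selection rule is fixed at p < 0.05 per pair, with a
feature declared distinguishable only when all 6 pairs are significant,
which is itself a strong conjunction.

## What the synthetic study does and does not show

The generator reproduces the study's *design* — activity levels,
insert configurations, setting grid, single-contour ROI — but not the
full physics of an acquisition: no scatter, randoms, attenuation,
reconstruction correlations beyond Gaussian blur, or count-rate
effects. Noise here is white before filtering, whereas OSEM noise is
spatially correlated. Consequently the pipeline's category counts
(e.g. 50/78 stable, 42 distinguishable at seed 1) characterize the
surrogate conditions, not a physical scanner, and are expected to be
more favourable than scanner measurements; the qualitative findings —
the post-filter dominating feature variation, TOF mattering least, and
heterogeneous-vs-homogeneous pairs being separable by GLCM
dissimilarity — are the claims the test suite checks (20-replicate
detection experiment, ≥ 80 % criterion).

## Problem sizes and determinism

The default study is 4 shapes × 21 settings × 78 features on a
100 × 100 × 60 grid (≈ 18 000 ROI voxels), ~10 s on one CPU; the
replicate experiment repeats the study 20 times extracting the GLCM
family only. Unit tests use a reduced 9-setting grid where only
pipeline plumbing (not the study conditions) is under test. All
randomness flows from one run seed through `numpy.random.SeedSequence`;
reruns with the same configuration are byte-identical, and every output
carries the configuration hash.
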