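# Methods

## Scope and assumptions

`gutquant` quantifies progenitor-cell accumulation (dysplasia) in the
*Drosophila* posterior midgut from multi-channel confocal z-stacks, plus
the cohort-level assays of such studies (mitotic counts, survival,
cultivable bacterial load, qPCR). The imaging model assumes:

- anisotropic voxels, default (z, y, x) = (2.0, 0.48147, 0.48147) µm —
  the acquisition geometry of a 63×/1.4 NA confocal with 2 µm slices;
- a bimodal nuclear-size population: diploid progenitors/EEs (small) and
  polyploid enterocytes (large), separable by major axis length;
- cytoplasmic GFP (progenitor label) sampled by a perinuclear ring,
  nuclear antigens (pH3, Prospero) sampled inside the nucleus;
- one global intensity threshold per stack is meaningful (uniform
  staining/illumination; no depth-dependent attenuation correction).

## Pipeline stages and defaults

| stage | default | rationale |
|---|---|---|
| median filter | disc radius 3 px, 2D per slice | a pixel-radius kernel under 2 µm slice spacing must not mix planes micrometres apart, so z is excluded |
| segmentation threshold | Otsu | scale-invariant; blank stacks return an empty labelling with a warning flag |
| seed separation | 3 µm | below the 4–6 µm diameter of diploid nuclei, so adjacent progenitors get distinct seeds |
| min component volume | 5 µm³ | debris floor, ~1/7 of a 2 µm-radius nucleus |
| ring expansion | 2 px, 26-connected steps, isotropic in voxel units | pixel-based protocol fidelity despite anisotropic z; contested voxels go to the Euclidean-nearest nucleus, recorded per cell |
| rolling ball | 20 px radius, per slice | implemented exactly as grayscale opening with a non-flat ball structuring element; features narrower than the ball survive |
| marker cutoff | 1.5 × internal-control median | median over mean for robustness to a minority of positives inside the control group |
| size threshold | KDE antimode between the two largest modes of control major-axis lengths (px); 1D Otsu fallback if unimodal | thresholds are frozen on controls and applied unchanged to all samples |

The segmenter is a classical threshold + distance-transform + watershed
composition: self-contained, deterministic, and oracle-testable. Users
of learned generalist segmenters can attach their label volumes through
`attach_external_labels`, which validates shape/dtype and relabels to a
contiguous id set without merging or splitting components.

### Which intensity statistic is thresholded

Ring and nuclear intensities are reported as integrated sums and as
per-voxel means. Classification defaults to the **mean** (per-voxel)
statistic: integrated intensity scales with compartment size, and ring
voxel counts differ roughly five-fold between diploid and polyploid
nuclei, so a single 1.5× cutoff on integrated intensity would
systematically miscall large GFP-negative cells. Normalizing per voxel
removes the size confound while keeping the 1.5×-of-control-median rule
intact; `marker_statistic="integrated"` restores sums for users who want
them. Ties (intensity exactly at the cutoff, length exactly at the size
threshold) go to the negative/large class — deterministic and
conservative for dysplasia claims.

## Synthetic scenes: what they emulate, and what they do not

`scene_synth` renders non-overlapping ellipsoidal nuclei (mild random
anisotropy, axis ratio ≤ 1.3, so major axes are nondegenerate) on the
default voxel grid, blurred by a Gaussian PSF (σ = 0.4 µm) and corrupted
by Poisson shot noise plus Gaussian read noise — the standard confocal
approximation. GFP is a 2 px in-plane shell around each nucleus (bright
for GFP⁺ cells, faint otherwise); pH3/Pros fill flagged nuclei; pH3⁺
cells are drawn only from the small class, since mitosis is a
progenitor behaviour. Cell placement enforces a ≥ 2 µm clearance
between nuclear surfaces so that a 2 px ring samples its own cell's
cytoplasm rather than a neighbour's shell — the assumption the
ring-mask method itself makes; placement retries are bounded (1000 per
cell) with an explicit "scene too crowded" error.

Preset scenes encode the two study conditions: a homeostatic control
(300 cells, 30% GFP⁺, 70% small) and constitutive-Toll dysplasia (600
cells, 93% GFP⁺, 88% small) on a 256×256×16 grid. Absolute per-frame
cell counts are not reported by gut-dysplasia studies, so these counts
are chosen for testability, not biological calibration.

What passing on synthetic scenes does **not** show: robustness to
depth-dependent attenuation, spatially varying background, touching or
overlapping nuclei, irregular (non-ellipsoidal) nuclear shapes, or
chromatic misregistration. Real guts have all of these; the synthetic
results bound algorithmic correctness, not acquisition robustness.

Survival cohorts are Weibull (default shape 3; exponential available)
parameterised by their median, with presets at the six study medians
(36/48 h systemic, 15.7/23.3 d oral, 37/45 d lifespan). Count cohorts
are negative binomial (dispersion 1) with a 10-fold infection preset.
qPCR tables are generated by inverting the 2^−ΔΔCt model; colony plates
are non-overlapping discs with a low-SNR flag when contrast falls below
twice the noise sd.

## Estimator details

- **LT50**: Kaplan–Meier product-limit curve; LT50 is the first time the
  curve reaches S(t) ≤ 0.5, linearly interpolated between the bracketing
  event times (reported LT50s like 15.7 d are non-step values, implying
  interpolation). A curve that never reaches 0.5 yields a flagged
  undefined LT50, not an error. The log-rank test uses the chi-square
  reference distribution and is cross-checked against a permutation null
  in the test suite.
- **Fold change**: ratio of group means with a seeded bootstrap
  percentile CI (2000 resamples by default).
- **CFU**: technical-replicate plates are averaged before scaling;
  CFU/gut = mean count × dilution ÷ plated fraction ÷ guts per
  homogenate. Zero counts report a below-detection flag with the
  detection limit (one colony), never −∞.
- **ΔΔCt**: each target replicate is normalized to the arithmetic mean
  of the two reference genes' Cts over the condition's replicates
  (equivalent to the geometric mean of linear quantities); the
  calibrator condition has expression 1 by construction.
- **OD₆₀₀**: linear through the single calibration point
  (OD 3 ≡ 5×10⁹ bacteria/ml).
- **Group tests**: Student's unpaired t (equal variances), Mann–Whitney
  (exact for small untied samples, verified against exhaustive
  permutation enumeration), one-way ANOVA; all two-sided.

## Numerical choices and degenerate inputs

- Single-voxel components get major axis length = one voxel extent and a
  `degenerate` flag.
- Watershed seed plateaus are merged into one marker before flooding,
  preventing plateau oversegmentation.
- Empty foreground segmentations, empty rings, and all-censored survival
  groups are flagged, not fatal; all-zero intensity controls are an
  error (there is no signal to normalize to).
- All resampling (bootstrap, permutation) is driven by explicit seeds;
  identical spec + seed reproduces scene arrays bit-for-bit.

## Problem sizes

Test and acceptance runs use the preset scenes (256×256×16, ≤ 600
cells), survival cohorts of n = 2000 (recovering preset medians within
5%), count cohorts of n = 10⁴ per group, and 10⁴-replicate null
simulations for test calibration; distribution-recovery checks use
n = 10⁵. These sizes put Monte-Carlo error well inside each check's
tolerance while keeping a full run in minutes on one CPU.

## Known limitations

- The watershed stand-in undersegments tightly clustered nuclei relative
  to learned segmenters (~95% recall on the default synthetic scene) and
  its defaults are calibrated on synthetic scenes only.
- Touching colonies on plates merge into one component; the count is
  conservative and merged blobs are flagged as area outliers
  (> 1.8× median area) rather than split.
- Ring masks assume perinuclear cytoplasm is the cell's own; in heavily
  crowded real tissue rings may sample neighbouring cells.
- qPCR amplification efficiency is assumed to be exactly 2 per cycle for
  all genes; no efficiency correction is applied.
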