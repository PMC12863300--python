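# gutquant

Quantitative analysis of *Drosophila* midgut confocal stacks and the
cohort statistics that accompany gut-dysplasia studies.

When Toll/NF-κB signalling is constitutively activated in intestinal
progenitors, the midgut epithelium fills with small-nucleus, GFP⁺
(esg-driven) progenitor cells at the expense of large polyploid
enterocytes. Quantifying that phenotype from 3D confocal stacks requires:
segmenting nuclei in strongly anisotropic z-stacks (0.48147 × 0.48147 µm
pixels, 2 µm slices), measuring nuclear size, sampling perinuclear
cytoplasm for GFP, and calling each cell's size class and marker status
against thresholds frozen on control guts. `gutquant` implements that
pipeline, the surrounding assay statistics — mitotic index and fold
change, Kaplan–Meier LT50 and log-rank, colony counting and log₁₀
CFU/gut, 2^−ΔΔCt relative expression with two reference genes, OD₆₀₀ →
cell-density conversion — and a ground-truthed synthetic-scene generator
so the whole chain is testable without microscope data.

## Method core

For each gut stack (channels: nuclear stain, GFP, pH3, Pros):

1. **Median filter** the nuclear channel, in-plane disc of radius 3 px.
2. **Segment nuclei in 3D**: Otsu threshold → anisotropy-aware Euclidean
   distance transform → smoothed distance maxima (≥ 3 µm apart) as seeds
   → seeded watershed → drop debris below 5 µm³. Externally produced
   label volumes (e.g. from a learned segmenter) can be attached instead.
3. **Morphometry**: per nucleus, the moment-based major axis length
   `L = 2·√(5·λ_max)` with `λ_max` the largest eigenvalue of the voxel
   second-central-moment matrix (the major axis of the ellipsoid with the
   same second moments), reported in px and µm.
4. **Ring masks**: each nucleus dilated by 2 px in 3D, nuclei subtracted;
   contested shell voxels go to the Euclidean-nearest nucleus.
5. **Background**: rolling-ball subtraction, 20 px radius per z-slice
   (grayscale opening with a ball structuring element).
6. **Classification**: the small/large size threshold is the antimode of
   a KDE over control-gut major-axis lengths (Otsu fallback if unimodal);
   marker positivity uses a 1.5× cutoff on fluorescence normalized to the
   internal-control median. Thresholds are frozen on controls and applied
   to all samples.
7. **Summaries**: per-gut totals and proportions (GFP⁺, small, large,
   pH3⁺, Pros⁺), group comparisons (Student's t, Mann–Whitney, one-way
   ANOVA, log-rank), LT50 as the linearly interpolated time the KM curve
   crosses S(t) = 0.5.

## Worked example

```python
import gutquant as gq
from gutquant.cli_io import RunConfig, analyze_scene_pair

control_grid, _ = gq.generate_gut_stack(gq.control_gut_spec())
sample_grid, truth = gq.generate_gut_stack(gq.dysplasia_gut_spec())
bundle = analyze_scene_pair(sample_grid, control_grid, RunConfig(),
                            gut_id="dysplasia")
s, m = bundle["summary"], bundle["model"]
print(s.total_cells, s.n_gfp, round(s.prop_gfp, 4), round(s.prop_small, 4))
print(round(m.size_threshold_px, 2), m.size_method)
```

prints

```
569 530 0.9315 0.8752
13.66 kde_antimode
```

The dysplasia preset renders 600 nuclei (93% GFP⁺, 88% small) on a
256×256×16 grid; the pipeline segments 569 of them and reports a GFP⁺
proportion of 93.2% and a small-nucleus proportion of 87.5% — the
dysplastic signature (more than 90% progenitor-marked cells, small
nuclei dominating) recovered end to end from pixels, with the size
threshold (13.66 px) derived from the control scene's bimodal
major-axis-length distribution. Survival works the same way:

```python
cohort = gq.generate_survival_cohort(
    gq.survival_preset("oral_control", n=2000, seed=5), group="oral_control")
gq.km_lt50(cohort).loc["oral_control", "lt50"]   # 22.95 (days; preset median 23.3)
```

A `gutquant` CLI wraps the same functions
(`simulate / segment / quantify / classify / summarize / survival / cfu /
qpcr / compare / run`); see `gutquant --help`.

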