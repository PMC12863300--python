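"""Ground-truthed synthetic inputs for every pipeline stage.

Confocal gut stacks are emulated as fields of non-overlapping ellipsoidal
nuclei (a bimodal size population: diploid progenitors vs polyploid
enterocytes) rendered on the microscope's anisotropic voxel grid
(0.48147 x 0.48147 x 2 um), with cytoplasmic GFP shells around a
configurable cell fraction, sparse pH3+ mitotic nuclei, Prospero+ nuclei,
Gaussian PSF blur and Poisson-Gaussian noise.  Survival cohorts, mitotic
count cohorts, colony-plate images and qPCR Ct tables are generated with
the statistical structure the downstream estimators assume, so parameter
recovery is testable without any microscope data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgproc import VoxelGrid

__all__ = [
    "DEFAULT_VOXEL_SPACING_UM",
    "SceneTooCrowdedError",
    "SceneSpec",
    "GroundTruth",
    "SurvivalSpec",
    "CountSpec",
    "PlateSpec",
    "PlateGroundTruth",
    "QpcrSpec",
    "SURVIVAL_PRESETS",
    "INFECTION_FOLD",
    "control_gut_spec",
    "dysplasia_gut_spec",
    "survival_preset",
    "infection_count_spec",
    "weibull_scale",
    "generate_gut_stack",
    "generate_survival_cohort",
    "generate_count_cohort",
    "generate_plate_image",
    "generate_qpcr_table",
]

#: Confocal voxel size (z, y, x) in micrometres.
DEFAULT_VOXEL_SPACING_UM = (2.0, 0.48147, 0.48147)

CHANNEL_NAMES = ("nuclear", "gfp", "ph3", "pros")


class SceneTooCrowdedError(RuntimeError):
    """Raised when the requested cell density cannot be placed without overlap."""


def _check_frac(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic gut stack.

    Radii are equivalent-sphere radii in um, drawn per cell from
    ``N(mean, sd)`` for the small (diploid) and large (polyploid) classes;
    nuclei get a mild random axis anisotropy (ratio <= ``anisotropy_max``)
    so major-axis measurements are nondegenerate.  ``noise`` is
    ``(gaussian_sd, poisson_scale)``: Gaussian read noise plus Poisson shot
    noise applied as ``Poisson(I * scale) / scale``.
    """

    shape_vox: tuple[int, int, int] = (16, 128, 128)
    voxel_spacing_um: tuple[float, float, float] = DEFAULT_VOXEL_SPACING_UM
    n_cells: int = 50
    frac_small: float = 0.7
    small_radius_um: tuple[float, float] = (2.0, 0.2)
    large_radius_um: tuple[float, float] = (4.5, 0.45)
    frac_gfp: float = 0.5
    frac_ph3: float = 0.05
    frac_pros: float = 0.1
    gfp_pos_intensity: float = 120.0
    gfp_neg_intensity: float = 20.0
    psf_sigma_um: float = 0.4
    noise: tuple[float, float] = (3.0, 1.0)
    seed: int = 0
    # rendering details
    nuclear_intensity: float = 200.0
    marker_intensity: float = 150.0
    anisotropy_max: float = 1.3
    #: clearance between nuclear surfaces; a 2 px ring plus 2 px shell never
    #: reach a neighbour's cytoplasm when surfaces are >= ~2 um apart
    min_gap_um: float = 2.0
    max_place_tries: int = 1000
    gfp_shell_px: int = 2

    def __post_init__(self):
        if len(self.shape_vox) != 3 or any(int(s) <= 0 for s in self.shape_vox):
            raise ValueError("shape_vox must be three positive integers")
        if any(float(s) <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("frac_small", "frac_gfp", "frac_ph3", "frac_pros"):
            _check_frac(name, getattr(self, name))
        if self.small_radius_um[0] >= self.large_radius_um[0]:
            raise ValueError("small mean radius must be below large mean radius")
        if min(self.gfp_pos_intensity, self.gfp_neg_intensity) < 0:
            raise ValueError("GFP intensities must be non-negative")
        if self.psf_sigma_um < 0 or any(float(v) < 0 for v in self.noise):
            raise ValueError("psf_sigma_um and noise parameters must be >= 0")
        if not 1.0 <= self.anisotropy_max:
            raise ValueError("anisotropy_max must be >= 1")
        object.__setattr__(self, "shape_vox", tuple(int(s) for s in self.shape_vox))
        object.__setattr__(
            self, "voxel_spacing_um", tuple(float(s) for s in self.voxel_spacing_um)
        )


@dataclass(frozen=True)
class GroundTruth:
    """True cell table and label volume of a generated scene.

    ``cells`` has one row per rendered nucleus (ids contiguous from 1)
    with centroid and semi-axes in um, size class and marker flags.
    """

    cells: pd.DataFrame
    labels: np.ndarray


def control_gut_spec(**overrides) -> SceneSpec:
    """Homeostatic control gut: moderate progenitor (GFP+) fraction."""
    kw = dict(
        shape_vox=(16, 256, 256),
        n_cells=300,
        frac_small=0.70,
        frac_gfp=0.30,
        frac_ph3=0.03,
        frac_pros=0.10,
        seed=1,
    )
    kw.update(overrides)
    return SceneSpec(**kw)


def dysplasia_gut_spec(**overrides) -> SceneSpec:
    """Constitutive-Toll dysplasia: crowded gut dominated by small GFP+ nuclei."""
    kw = dict(
        shape_vox=(16, 256, 256),
        n_cells=600,
        frac_small=0.88,
        frac_gfp=0.93,
        frac_ph3=0.05,
        frac_pros=0.08,
        seed=11,
    )
    kw.update(overrides)
    return SceneSpec(**kw)


# ---------------------------------------------------------------------------
# gut stack generation
# ---------------------------------------------------------------------------


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw sizes, flags and non-overlapping positions for every cell."""
    n = spec.n_cells
    n_small = int(round(spec.frac_small * n))
    size_class = np.array(["small"] * n_small + ["large"] * (n - n_small))

    mean_s, sd_s = spec.small_radius_um
    mean_l, sd_l = spec.large_radius_um
    radii = np.empty(n)
    radii[:n_small] = np.clip(rng.normal(mean_s, sd_s, n_small), 0.5 * mean_s, None)
    radii[n_small:] = np.clip(rng.normal(mean_l, sd_l, n - n_small), 0.5 * mean_l, None)

    # mild per-axis anisotropy: factors in [1/sqrt(a_max), sqrt(a_max)]
    lim = math.sqrt(spec.anisotropy_max)
    factors = rng.uniform(1.0 / lim, lim, size=(n, 3))
    semi_axes = radii[:, None] * factors  # (z, y, x) semi-axes in um

    # marker flags: exact counts, assigned uniformly at random
    gfp = np.zeros(n, dtype=int)
    gfp[rng.permutation(n)[: int(round(spec.frac_gfp * n))]] = 1
    pros = np.zeros(n, dtype=int)
    pros[rng.permutation(n)[: int(round(spec.frac_pros * n))]] = 1
    ph3 = np.zeros(n, dtype=int)
    n_ph3 = int(round(spec.frac_ph3 * n))
    small_idx = np.flatnonzero(size_class == "small")
    if n_ph3 > small_idx.size:
        raise ValueError(
            f"frac_ph3={spec.frac_ph3} requests {n_ph3} mitotic cells but only "
            f"{small_idx.size} small (progenitor-size) cells exist"
        )
    ph3[rng.choice(small_idx, size=n_ph3, replace=False)] = 1

    # placement: largest first, rejection sampling with a bounded retry budget
    extent_um = np.array(spec.shape_vox) * np.array(spec.voxel_spacing_um)
    order = np.argsort(-radii)
    max_semi = semi_axes.max(axis=1)
    centers = np.full((n, 3), np.nan)
    placed_r: list[float] = []
    placed_c: list[np.ndarray] = []
    for i in order:
        margin = np.minimum(semi_axes[i] + np.array(spec.voxel_spacing_um), extent_um / 2)
        lo, hi = margin, extent_um - margin
        ok = False
        for _ in range(spec.max_place_tries):
            c = rng.uniform(lo, hi)
            if placed_c:
                d = np.linalg.norm(np.array(placed_c) - c, axis=1)
                min_d = np.array(placed_r) + max_semi[i] + spec.min_gap_um
                if np.any(d <= min_d):
                    continue
            ok = True
            break
        if not ok:
            raise SceneTooCrowdedError(
                f"could not place cell {len(placed_c) + 1}/{n} after "
                f"{spec.max_place_tries} tries: scene too crowded"
            )
        centers[i] = c
        placed_c.append(c)
        placed_r.append(max_semi[i])

    cells = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "centroid_z_um": centers[:, 0],
            "centroid_y_um": centers[:, 1],
            "centroid_x_um": centers[:, 2],
            "semi_z_um": semi_axes[:, 0],
            "semi_y_um": semi_axes[:, 1],
            "semi_x_um": semi_axes[:, 2],
            "size_class": size_class,
            "gfp": gfp,
            "ph3": ph3,
            "pros": pros,
        }
    )
    return cells


def _render_labels(spec: SceneSpec, cells: pd.DataFrame) -> np.ndarray:
    labels = np.zeros(spec.shape_vox, dtype=np.int32)
    spacing = np.array(spec.voxel_spacing_um)
    for row in cells.itertuples(index=False):
        c = np.array([row.centroid_z_um, row.centroid_y_um, row.centroid_x_um])
        s = np.array([row.semi_z_um, row.semi_y_um, row.semi_x_um])
        lo = np.maximum(np.floor((c - s) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + s) / spacing).astype(int) + 1, spec.shape_vox)
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[a], hi[a]) * spacing[a] - c[a] for a in range(3)),
            indexing="ij",
        )
        inside = (zz / s[0]) ** 2 + (yy / s[1]) ** 2 + (xx / s[2]) ** 2 <= 1.0
        sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub[inside] = row.id
    return labels


def _inplane_dilate(mask: np.ndarray, px: int) -> np.ndarray:
    if px <= 0:
        return mask
    structure = np.ones((1, 3, 3), dtype=bool)
    return ndi.binary_dilation(mask, structure=structure, iterations=px)


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    gaussian_sd, poisson_scale = spec.noise
    out = img.astype(np.float64)
    if poisson_scale > 0:
        out = rng.poisson(out * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


def generate_gut_stack(spec: SceneSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render a 4-channel gut stack (nuclear, GFP, pH3, Pros) with ground truth.

    Nuclei are solid ellipsoids blurred by a Gaussian PSF; cytoplasmic GFP
    is rendered in a 2-px in-plane shell around each nucleus (bright for
    GFP+ cells, faint background level otherwise); pH3 and Pros light up
    within flagged nuclei.  Noise is applied last.  Identical spec+seed
    gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_cells == 0:
        cells = pd.DataFrame(
            {
                "id": pd.Series([], dtype=int),
                "centroid_z_um": pd.Series([], dtype=float),
                "centroid_y_um": pd.Series([], dtype=float),
                "centroid_x_um": pd.Series([], dtype=float),
                "semi_z_um": pd.Series([], dtype=float),
                "semi_y_um": pd.Series([], dtype=float),
                "semi_x_um": pd.Series([], dtype=float),
                "size_class": pd.Series([], dtype=str),
                "gfp": pd.Series([], dtype=int),
                "ph3": pd.Series([], dtype=int),
                "pros": pd.Series([], dtype=int),
            }
        )
        labels = np.zeros(spec.shape_vox, dtype=np.int32)
    else:
        cells = _place_cells(spec, rng)
        labels = _render_labels(spec, cells)

    nuc_mask = labels > 0
    channels = np.zeros((4,) + spec.shape_vox, dtype=np.float64)
    channels[0][nuc_mask] = spec.nuclear_intensity

    if spec.n_cells:
        gfp_ids = cells.loc[cells.gfp == 1, "id"].to_numpy()
        pos_nuc = np.isin(labels, gfp_ids)
        neg_nuc = nuc_mask & ~pos_nuc
        pos_shell = _inplane_dilate(pos_nuc, spec.gfp_shell_px) & ~nuc_mask
        neg_shell = _inplane_dilate(neg_nuc, spec.gfp_shell_px) & ~nuc_mask & ~pos_shell
        channels[1][pos_shell] = spec.gfp_pos_intensity
        channels[1][neg_shell] = spec.gfp_neg_intensity
        for ci, col in ((2, "ph3"), (3, "pros")):
            ids = cells.loc[cells[col] == 1, "id"].to_numpy()
            if ids.size:
                channels[ci][np.isin(labels, ids)] = spec.marker_intensity

    if spec.psf_sigma_um > 0:
        sigma = [spec.psf_sigma_um / s for s in spec.voxel_spacing_um]
        for c in range(4):
            channels[c] = ndi.gaussian_filter(channels[c], sigma=sigma)

    noisy = np.stack([_apply_noise(channels[c], spec, rng) for c in range(4)])
    grid = VoxelGrid(noisy, spec.voxel_spacing_um, CHANNEL_NAMES)
    return grid, GroundTruth(cells=cells, labels=labels)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

#: Median survival times of the study cohorts: systemic S. aureus infection
#: with Toll silenced in the fat body vs control (hours), oral S. aureus
#: infection with Toll silenced in gut progenitors vs control (days), and
#: uninfected lifespan under constitutive Toll activity vs control (days).
SURVIVAL_PRESETS: dict[str, tuple[float, str]] = {
    "systemic_tollRNAi": (36.0, "h"),
    "systemic_control": (48.0, "h"),
    "oral_tollRNAi": (15.7, "days"),
    "oral_control": (23.3, "days"),
    "lifespan_toll10b": (37.0, "days"),
    "lifespan_control": (45.0, "days"),
}


@dataclass(frozen=True)
class SurvivalSpec:
    """Event-time generator: Weibull (default shape 3) or exponential."""

    n: int
    median_time: float
    distribution: str = "weibull"
    shape: float = 3.0
    time_unit: str = "days"
    censor_time: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.median_time <= 0:
            raise ValueError("median_time must be positive")
        if self.distribution not in ("weibull", "exponential"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.shape <= 0:
            raise ValueError("shape must be positive")


def weibull_scale(median_time: float, shape: float) -> float:
    """Scale parameter of a Weibull with the given median.

    For shape 1 (exponential) this reduces to ``median / ln 2``.
    """
    return median_time / math.log(2.0) ** (1.0 / shape)


def survival_preset(name: str, n: int = 2000, seed: int = 0, **overrides) -> SurvivalSpec:
    median, unit = SURVIVAL_PRESETS[name]
    kw = dict(n=n, median_time=median, time_unit=unit, seed=seed)
    kw.update(overrides)
    return SurvivalSpec(**kw)


def generate_survival_cohort(spec: SurvivalSpec, group: str = "cohort") -> pd.DataFrame:
    """Draw ``n`` (time, event) rows; sample median converges to ``median_time``."""
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 if spec.distribution == "exponential" else spec.shape
    scale = weibull_scale(spec.median_time, shape)
    times = scale * rng.weibull(shape, spec.n)
    events = np.ones(spec.n, dtype=int)
    if spec.censor_time is not None:
        censored = times > spec.censor_time
        times = np.where(censored, spec.censor_time, times)
        events = np.where(censored, 0, 1)
    return pd.DataFrame(
        {
            "individual_id": np.arange(1, spec.n + 1),
            "group": group,
            "time": times,
            "event": events,
        }
    )


# ---------------------------------------------------------------------------
# mitotic count cohorts
# ---------------------------------------------------------------------------

#: Oral P. aeruginosa infection raises the whole-gut mitotic index ~10-fold.
INFECTION_FOLD = 10.0


@dataclass(frozen=True)
class CountSpec:
    """Negative-binomial per-gut pH3+ count cohorts, control vs treated."""

    n_per_group: int
    baseline_mean: float = 2.0
    fold: float = INFECTION_FOLD
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.baseline_mean <= 0 or self.fold <= 0:
            raise ValueError("baseline_mean and fold must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def infection_count_spec(n_per_group: int = 30, seed: int = 0, **overrides) -> CountSpec:
    kw = dict(n_per_group=n_per_group, fold=INFECTION_FOLD, seed=seed)
    kw.update(overrides)
    return CountSpec(**kw)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    # NB with mean m and size r: variance m + m^2/r
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, n)


def generate_count_cohort(spec: CountSpec) -> pd.DataFrame:
    """Control counts ~ NB(baseline_mean); treated ~ NB(baseline_mean * fold)."""
    rng = np.random.default_rng(spec.seed)
    control = _nb_draw(rng, spec.baseline_mean, spec.dispersion, spec.n_per_group)
    treated = _nb_draw(rng, spec.baseline_mean * spec.fold, spec.dispersion, spec.n_per_group)
    return pd.DataFrame(
        {
            "group": ["control"] * spec.n_per_group + ["treated"] * spec.n_per_group,
            "count": np.concatenate([control, treated]),
        }
    )


# ---------------------------------------------------------------------------
# colony plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateSpec:
    """Synthetic agar plate photograph: bright colonies on a flat background."""

    image_size_px: tuple[int, int] = (512, 512)
    n_colonies: int = 50
    colony_radius_px: tuple[float, float] = (6.0, 1.0)
    background: float = 30.0
    contrast: float = 60.0
    noise_sd: float = 4.0
    min_gap_px: float = 2.0
    seed: int = 0
    max_place_tries: int = 1000

    def __post_init__(self):
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.colony_radius_px[0] <= 0:
            raise ValueError("colony radius must be positive")


@dataclass(frozen=True)
class PlateGroundTruth:
    n_colonies: int
    centers: np.ndarray
    radii: np.ndarray
    low_snr: bool


def generate_plate_image(spec: PlateSpec) -> tuple[np.ndarray, PlateGroundTruth]:
    """Render non-overlapping colonies; flags low SNR when contrast ~ noise."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    img = np.full((h, w), spec.background, dtype=np.float64)

    mean_r, sd_r = spec.colony_radius_px
    radii = np.clip(rng.normal(mean_r, sd_r, spec.n_colonies), 0.5 * mean_r, None)
    centers = np.empty((spec.n_colonies, 2))
    for i in range(spec.n_colonies):
        r = radii[i]
        ok = False
        for _ in range(spec.max_place_tries):
            c = rng.uniform([r + 1, r + 1], [h - r - 1, w - r - 1])
            if i and np.any(
                np.linalg.norm(centers[:i] - c, axis=1)
                <= radii[:i] + r + spec.min_gap_px
            ):
                continue
            ok = True
            break
        if not ok:
            raise SceneTooCrowdedError(
                f"could not place colony {i + 1}/{spec.n_colonies}: plate too crowded"
            )
        centers[i] = c
        yy, xx = np.ogrid[:h, :w]
        img[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2] += spec.contrast

    img = ndi.gaussian_filter(img, sigma=1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)
    low_snr = spec.noise_sd > 0 and spec.contrast < 2.0 * spec.noise_sd
    truth = PlateGroundTruth(
        n_colonies=spec.n_colonies, centers=centers, radii=radii, low_snr=low_snr
    )
    return img, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSpec:
    """Ct-table generator inverted from the 2^-ddCt model.

    The first condition is the calibrator.  Target Ct is lowered by
    ``log2(fold)`` in each condition; the two reference genes stay flat
    across conditions up to Ct noise, so applying 2^-ddCt recovers
    ``true_fold_per_condition`` in expectation.
    """

    target: str = "hep"
    reference_genes: tuple[str, str] = ("RpL32", "Gapdh1")
    conditions: tuple[str, ...] = ("control", "toll10b")
    true_fold_per_condition: tuple[float, ...] = (1.0, 10.0)
    n_replicates: int = 3
    ct_noise_sd: float = 0.2
    target_base_ct: float = 24.0
    ref_base_cts: tuple[float, float] = (16.0, 18.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.reference_genes) < 2:
            raise ValueError("at least two reference genes are required")
        if len(self.true_fold_per_condition) != len(self.conditions):
            raise ValueError("one true fold per condition is required")
        if any(f <= 0 for f in self.true_fold_per_condition):
            raise ValueError("true folds must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def generate_qpcr_table(spec: QpcrSpec) -> pd.DataFrame:
    """Tidy Ct table with columns (gene, condition, replicate, ct)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond, fold in zip(spec.conditions, spec.true_fold_per_condition):
        for rep in range(1, spec.n_replicates + 1):
            ct = spec.target_base_ct - math.log2(fold)
            rows.append((spec.target, cond, rep, ct + rng.normal(0, spec.ct_noise_sd)))
            for gene, base in zip(spec.reference_genes, spec.ref_base_cts):
                rows.append((gene, cond, rep, base + rng.normal(0, spec.ct_noise_sd)))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
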