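"""Pre-filtering and 3D nuclei segmentation.

The nuclear channel of a confocal z-stack is median filtered per slice,
thresholded, and split into individual nuclei by a distance-transform
seeded watershed.  The segmenter is a self-contained classical stand-in
for generalist learned models; externally produced label volumes can be
attached through :func:`attach_external_labels`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "SegmentationParams",
    "median_filter_stack",
    "segment_nuclei",
    "attach_external_labels",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A multi-channel 3D intensity stack with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Non-negative intensities, channel first.
    voxel_spacing_um : tuple of float
        Physical voxel size ``(z, y, x)`` in micrometres.
    channel_names : list of str
        One name per channel, e.g. ``["nuclear", "gfp", "ph3", "pros"]``.
    """

    data: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 4:
            raise ValueError(f"expected 4D (C, Z, Y, X) data, got {data.ndim}D")
        spacing = tuple(float(s) for s in self.voxel_spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 strictly positive values, got {spacing}")
        names = tuple(str(n) for n in self.channel_names)
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[0]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_spacing_um", spacing)
        object.__setattr__(self, "channel_names", names)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (Z, Y, X) view."""
        return self.data[self.channel_index(name)]

    def with_channel(self, name: str, values: np.ndarray) -> "VoxelGrid":
        """Return a copy of the grid with one channel replaced."""
        values = np.asarray(values)
        if values.shape != self.spatial_shape:
            raise ValueError(f"channel shape {values.shape} != {self.spatial_shape}")
        data = self.data.copy()
        data[self.channel_index(name)] = values
        return dataclasses.replace(self, data=data)


@dataclass(frozen=True)
class LabelVolume:
    """Integer-labelled 3D segmentation; 0 is background, labels are 1..K."""

    labels: np.ndarray
    empty_warning: bool = False

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be 3D (Z, Y, X)")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got {labels.dtype}")
        object.__setattr__(self, "labels", labels)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the classical watershed segmenter.

    threshold : "otsu" or an absolute intensity. Otsu keeps the result
        invariant to global intensity rescaling.
    seed_separation_um : minimum distance between watershed seeds; the
        default of 3 um sits below the ~4-6 um diameter of diploid nuclei.
    smooth_sigma_um : Gaussian smoothing of the distance map before peak
        detection, suppressing spurious maxima from a ragged mask boundary.
    min_volume_um3 : components smaller than this are dropped as debris.
    """

    threshold: str | float = "otsu"
    seed_separation_um: float = 3.0
    smooth_sigma_um: float = 0.6
    min_volume_um3: float = 5.0


def median_filter_stack(grid: VoxelGrid, channel: str, radius_px: int = 3) -> VoxelGrid:
    """Median filter one channel with an in-plane disc of ``radius_px``.

    Filtering is 2D per z-slice: with 2 um slice spacing against ~0.48 um
    pixels, a 3D ball of a few *pixels* would mix planes micrometres
    apart, so the z axis is excluded.  ``radius_px=0`` is the identity.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    img = grid.channel(channel)
    if radius_px == 0:
        return grid.with_channel(channel, img.copy())
    footprint = disk(radius_px)[np.newaxis, :, :]
    filtered = ndi.median_filter(img, footprint=footprint, mode="nearest")
    return grid.with_channel(channel, filtered)


def _seed_footprint(separation_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    half = [max(1, int(round(separation_um / s))) for s in spacing]
    return np.ones(tuple(2 * h + 1 for h in half), dtype=bool)


def segment_nuclei(
    grid: VoxelGrid,
    channel: str,
    params: SegmentationParams | None = None,
) -> LabelVolume:
    """Segment nuclei from the (median-filtered) nuclear channel.

    Pipeline: global threshold (Otsu by default) -> anisotropy-aware
    Euclidean distance transform -> Gaussian-smoothed distance maxima as
    seeds (minimum separation in um) -> seeded watershed restricted to the
    foreground -> removal of components below ``min_volume_um3``.

    An empty foreground is not an error: the result carries
    ``empty_warning=True`` and zero labels.
    """
    params = params or SegmentationParams()
    img = np.asarray(grid.channel(channel), dtype=np.float64)
    spacing = grid.voxel_spacing_um

    if params.threshold == "otsu":
        if np.ptp(img) == 0:
            return LabelVolume(np.zeros(img.shape, np.int32), empty_warning=True)
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold)
    fg = img > thr
    if not fg.any():
        return LabelVolume(np.zeros(img.shape, np.int32), empty_warning=True)

    dist = ndi.distance_transform_edt(fg, sampling=spacing)
    sigma = [params.smooth_sigma_um / s for s in spacing]
    dist_s = ndi.gaussian_filter(dist, sigma=sigma)

    peaks = peak_local_max(
        dist_s,
        footprint=_seed_footprint(params.seed_separation_um, spacing),
        labels=fg,
        exclude_border=False,
    )
    peak_mask = np.zeros(img.shape, dtype=bool)
    peak_mask[tuple(peaks.T)] = True
    # merge peaks touching each other (plateaus) into a single seed
    markers, _ = ndi.label(peak_mask, structure=np.ones((3, 3, 3)))
    labels = watershed(-dist_s, markers=markers, mask=fg)

    voxel_vol = float(np.prod(spacing))
    min_vox = int(np.ceil(params.min_volume_um3 / voxel_vol))
    if min_vox > 1:
        counts = np.bincount(labels.ravel())
        kill = np.flatnonzero(counts < min_vox)
        if kill.size:
            labels[np.isin(labels, kill[kill > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    return LabelVolume(labels, empty_warning=labels.max() == 0)


def attach_external_labels(grid: VoxelGrid, labels: np.ndarray | str) -> LabelVolume:
    """Validate an externally produced label volume and relabel to 1..K.

    Plug-in seam for users segmenting with a learned model: accepts an
    integer array (or a TIFF path) matched to ``grid``'s spatial shape,
    and remaps arbitrary label ids to a contiguous set while preserving
    geometry.
    """
    if isinstance(labels, (str, bytes)) or hasattr(labels, "__fspath__"):
        import tifffile

        labels = tifffile.imread(labels)
    labels = np.asarray(labels)
    if labels.shape != grid.spatial_shape:
        raise ValueError(
            f"label shape {labels.shape} does not match stack {grid.spatial_shape}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
    relabelled, _, _ = relabel_sequential(labels)
    return LabelVolume(relabelled.astype(np.int32))
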