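"""Threshold derivation from control populations and per-cell calling.

The size threshold separating diploid (small) from polyploid (large)
nuclei is read off the control sample's major-axis-length distribution:
the antimode of a kernel density estimate between its two largest modes,
frozen and applied to all other samples.  Marker positivity (GFP, pH3,
Pros) uses a 1.5x cutoff on fluorescence normalized to the median of an
internal control group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

__all__ = [
    "ThresholdModel",
    "SizeThreshold",
    "IntensityCutoff",
    "derive_size_threshold",
    "classify_size",
    "derive_intensity_cutoff",
    "call_marker",
    "fit_threshold_model",
    "classify_cells",
]

SIZE_COLUMN = "major_axis_len_px"


@dataclass(frozen=True)
class SizeThreshold:
    """Derived small/large boundary with provenance."""

    threshold_px: float
    method: str  # "kde_antimode" or "otsu_fallback"
    n_control: int


@dataclass(frozen=True)
class IntensityCutoff:
    """Marker cutoff = factor x internal-control median."""

    cutoff: float
    normalization: float
    factor: float
    n_control: int


@dataclass
class ThresholdModel:
    """Frozen classification model derived from a control population."""

    size_threshold_px: float
    size_method: str
    intensity_cutoffs: dict[str, float] = field(default_factory=dict)
    normalization: dict[str, float] = field(default_factory=dict)
    marker_columns: dict[str, str] = field(default_factory=dict)
    cutoff_factor: float = 1.5
    control_reference: str = ""
    n_control: int = 0
    seed: int | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _kde_antimode(values: np.ndarray) -> float | None:
    """Interior minimum of the KDE between its two largest modes, or None."""
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = np.flatnonzero(interior) + 1
    if len(modes) < 2:
        return None
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        return None
    return float(grid[lo + np.argmin(dens[lo : hi + 1])])


def derive_size_threshold(
    control_records: pd.DataFrame | np.ndarray, min_recommended: int = 50
) -> SizeThreshold:
    """Size threshold from a control sample's major-axis lengths (px).

    The density of cells against major axis length is bimodal in control
    guts (diploid progenitors vs polyploid enterocytes); the threshold is
    the KDE antimode between the two largest modes.  A unimodal control
    falls back to 1D Otsu, recorded in the result's method.  Fewer than 2
    nuclei is an error; fewer than ``min_recommended`` warns.
    """
    if isinstance(control_records, pd.DataFrame):
        values = control_records[SIZE_COLUMN].to_numpy(dtype=float)
    else:
        values = np.asarray(control_records, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError(f"need at least 2 control nuclei, got {len(values)}")
    if len(values) < min_recommended:
        import warnings

        warnings.warn(
            f"only {len(values)} control nuclei; >= {min_recommended} recommended",
            stacklevel=2,
        )
    antimode = _kde_antimode(values) if np.ptp(values) > 0 else None
    if antimode is None:
        return SizeThreshold(
            threshold_px=float(threshold_otsu(values)),
            method="otsu_fallback",
            n_control=len(values),
        )
    return SizeThreshold(threshold_px=antimode, method="kde_antimode", n_control=len(values))


def classify_size(records: pd.DataFrame, model: ThresholdModel) -> pd.Series:
    """'small' iff major axis length (px) < threshold; ties go to 'large'."""
    lengths = records[SIZE_COLUMN].to_numpy(dtype=float)
    return pd.Series(
        np.where(lengths < model.size_threshold_px, "small", "large"),
        index=records.index,
        name="size_class",
    )


def derive_intensity_cutoff(
    control_intensities: np.ndarray | pd.Series, factor: float = 1.5
) -> IntensityCutoff:
    """Cutoff = ``factor`` x median intensity of the internal control group.

    The control median is the normalization constant; the median (rather
    than the mean) keeps the constant robust to a minority of positive
    cells inside the control sample.  An all-zero control carries no
    signal to normalize and raises.
    """
    values = np.asarray(control_intensities, dtype=float)
    if len(values) == 0:
        raise ValueError("control group is empty")
    norm = float(np.median(values))
    if norm <= 0:
        raise ValueError("control intensities are all zero; nothing to normalize to")
    return IntensityCutoff(
        cutoff=factor * norm, normalization=norm, factor=factor, n_control=len(values)
    )


def call_marker(records: pd.DataFrame, model: ThresholdModel, channel: str) -> pd.Series:
    """Positive (1) iff the marker intensity strictly exceeds the cutoff."""
    if channel not in model.intensity_cutoffs:
        raise KeyError(f"no cutoff for channel {channel!r} in model")
    column = model.marker_columns.get(channel, f"{channel}_ring_sum")
    if column not in records.columns:
        raise KeyError(f"records lack intensity column {column!r}")
    values = records[column].to_numpy(dtype=float)
    return pd.Series(
        (values > model.intensity_cutoffs[channel]).astype(int),
        index=records.index,
        name=channel,
    )


def fit_threshold_model(
    control_records: pd.DataFrame,
    marker_columns: dict[str, str],
    factor: float = 1.5,
    control_reference: str = "",
    seed: int | None = None,
) -> ThresholdModel:
    """Derive and freeze every threshold from one control sample.

    ``marker_columns`` maps each marker channel to the records column the
    cutoff applies to (e.g. ``{"gfp": "gfp_ring_mean"}``).
    """
    size = derive_size_threshold(control_records)
    cutoffs: dict[str, float] = {}
    norms: dict[str, float] = {}
    for channel, column in marker_columns.items():
        cut = derive_intensity_cutoff(control_records[column], factor=factor)
        cutoffs[channel] = cut.cutoff
        norms[channel] = cut.normalization
    return ThresholdModel(
        size_threshold_px=size.threshold_px,
        size_method=size.method,
        intensity_cutoffs=cutoffs,
        normalization=norms,
        marker_columns=dict(marker_columns),
        cutoff_factor=factor,
        control_reference=control_reference,
        n_control=size.n_control,
        seed=seed,
    )


def classify_cells(records: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Per-cell calls: size class plus 0/1 for every marker in the model."""
    calls = pd.DataFrame({"label": records["label"].to_numpy()})
    calls["size_class"] = classify_size(records, model).to_numpy()
    for channel in model.intensity_cutoffs:
        calls[channel] = call_marker(records, model, channel).to_numpy()
    return calls
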