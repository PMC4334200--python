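"""Quantification of autophagy from multi-channel field images.

The assay: primary muscle cultures express a GFP-tagged Atg8a reporter only
in muscle cells; autophagosomes appear as bright GFP puncta on top of the
diffuse cytoplasmic/nuclear reporter signal, and muscles are identified by
their bright phalloidin (actin) stain.  The per-field readout is the
*autophagy index* — total puncta area divided by total muscle area.

Operations
----------
- :func:`segment_muscle` — actin-based muscle mask.
- :func:`detect_puncta_granularity` — top-hat + robust-threshold spot
  detector with a size band (a documented stand-in for the proprietary
  granularity module used on the original screen images).
- :func:`rats_threshold` (re-exported from :mod:`myoscreen.rats`) and
  :func:`count_puncta` — local thresholding and object counting used for
  single-muscle confocal sections.
- :func:`autophagy_index`, :func:`max_intensity_projection`,
  :func:`manders_overlap`, :func:`flux_ratio`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import median_abs_deviation
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu

from .rats import RatsParams, RatsResult, rats_threshold

__all__ = [
    "ImageField",
    "MuscleMask",
    "PunctaSet",
    "PunctumObject",
    "MuscleSegParams",
    "GranularityParams",
    "RatsParams",
    "RatsResult",
    "MissingChannelError",
    "segment_muscle",
    "detect_puncta_granularity",
    "rats_threshold",
    "max_intensity_projection",
    "autophagy_index",
    "count_puncta",
    "manders_overlap",
    "flux_ratio",
]


class MissingChannelError(KeyError):
    """A required channel role is absent from the field."""


@dataclass
class ImageField:
    """A multi-channel 2-D field image.

    ``channels`` maps a role name (``gfp``, ``actin``, ``nuclear``, ``red``)
    to a 2-D float raster.  All rasters must share one shape and contain
    finite, non-negative intensities.  Coordinates are row-major with the
    origin at the top-left, 0-based.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # um/px, informational
    field_id: str = ""
    well_id: str = ""
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for role, a in self.channels.items():
            a = np.asarray(a, dtype=np.float64)
            if a.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2-D raster")
            if not np.isfinite(a).all():
                raise ValueError(f"channel {role!r} has non-finite intensities")
            if (a < 0).any():
                raise ValueError(f"channel {role!r} has negative intensities")
            self.channels[role] = a

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise MissingChannelError(
                f"field {self.field_id!r} has no {role!r} channel "
                f"(present: {sorted(self.channels)})"
            ) from None


class MuscleMask(NamedTuple):
    mask: np.ndarray
    n_muscles: int
    total_area: int


class PunctumObject(NamedTuple):
    label: int
    centroid: tuple[float, float]
    area: int
    mean_intensity: float


@dataclass(frozen=True)
class PunctaSet:
    """Labeled puncta plus the binary mask they were extracted from."""

    mask: np.ndarray
    objects: tuple[PunctumObject, ...]
    total_area: int

    def __post_init__(self) -> None:
        if self.total_area != int(np.count_nonzero(self.mask)):
            raise ValueError("total_area inconsistent with mask")
        if sum(o.area for o in self.objects) != self.total_area:
            raise ValueError("object areas do not sum to total_area")

    @property
    def centroids(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 2))
        return np.array([o.centroid for o in self.objects])

    def __len__(self) -> int:
        return len(self.objects)


@dataclass(frozen=True)
class MuscleSegParams:
    """Muscle segmentation from the actin channel.

    Smooth -> threshold (Otsu by default) -> morphological closing -> drop
    components below ``min_area``.  Non-muscle cells stain far more weakly
    with phalloidin than muscle ribbons and are also much smaller, so both
    the threshold and the area filter reject them.
    """

    smooth_sigma: float = 2.0
    threshold: float | str = "otsu"
    closing_radius: int = 3
    min_area: int = 500
    connectivity: int = 4

    def validate(self) -> None:
        if self.smooth_sigma < 0 or self.closing_radius < 0 or self.min_area < 0:
            raise ValueError("segmentation parameters must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class GranularityParams:
    """Spot-detection parameters (top-hat + robust threshold + size band).

    ``tophat_radius`` must exceed the radius of the largest expected punctum
    so the white top-hat isolates puncta while flattening the diffuse
    reporter signal and the (larger) nuclei.  The threshold is
    ``median + k_mad * MAD`` of top-hat values inside the muscle mask, with
    the MAD scaled to be consistent with a normal standard deviation.
    """

    tophat_radius: int = 8
    k_mad: float = 4.0
    size_band: tuple[int, int] = (4, 2000)
    connectivity: int = 4

    def validate(self) -> None:
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.k_mad < 0:
            raise ValueError("k_mad must be >= 0")
        lo, hi = self.size_band
        if not lo < hi:
            raise ValueError("size_band must satisfy min < max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def segment_muscle(
    field: ImageField, params: MuscleSegParams | None = None
) -> MuscleMask:
    """Segment muscle cells from the actin (phalloidin) channel."""
    params = params or MuscleSegParams()
    params.validate()
    actin = field.channel("actin")

    sm = gaussian(actin, sigma=params.smooth_sigma, preserve_range=True)
    if sm.max() == sm.min():  # blank field: nothing to threshold
        empty = np.zeros(actin.shape, dtype=bool)
        return MuscleMask(mask=empty, n_muscles=0, total_area=0)
    if params.threshold == "otsu":
        t = threshold_otsu(sm)
    else:
        t = float(params.threshold)
    bw = sm > t
    if params.closing_radius > 0:
        bw = morphology.closing(bw, morphology.disk(params.closing_radius))
    conn = _skimage_connectivity(params.connectivity)
    labels = measure.label(bw, connectivity=conn)
    keep = np.flatnonzero(np.bincount(labels.ravel())[1:] >= params.min_area) + 1
    bw = np.isin(labels, keep)
    return MuscleMask(mask=bw, n_muscles=len(keep), total_area=int(bw.sum()))


def detect_puncta_granularity(
    field: ImageField,
    muscle: MuscleMask,
    params: GranularityParams | None = None,
) -> PunctaSet:
    """Detect GFP puncta inside the muscle mask.

    White top-hat with a disk of ``tophat_radius`` removes the diffuse
    cytoplasmic and nuclear reporter signal; the remainder is thresholded at
    ``median + k_mad * MAD`` of top-hat values inside the muscle, and
    connected components are kept when their area lies within the size band.
    Because the threshold is relative to robust statistics of the same
    field, the detector is invariant under uniform intensity rescaling.
    """
    params = params or GranularityParams()
    params.validate()
    if muscle.total_area == 0:
        raise ValueError("empty muscle mask: autophagy index undefined for this field")
    gfp = field.channel("gfp")

    tophat = morphology.white_tophat(gfp, footprint=morphology.disk(params.tophat_radius))
    inside = tophat[muscle.mask]
    cut = float(np.median(inside)) + params.k_mad * float(
        median_abs_deviation(inside, scale="normal")
    )
    hot = (tophat > cut) & muscle.mask

    conn = _skimage_connectivity(params.connectivity)
    labels = measure.label(hot, connectivity=conn)
    lo, hi = params.size_band
    mask = np.zeros_like(hot)
    objects: list[PunctumObject] = []
    for region in measure.regionprops(labels, intensity_image=gfp):
        if lo <= region.area <= hi:
            mask[labels == region.label] = True
            objects.append(
                PunctumObject(
                    label=len(objects) + 1,
                    centroid=(float(region.centroid[0]), float(region.centroid[1])),
                    area=int(region.area),
                    mean_intensity=float(region.intensity_mean),
                )
            )
    return PunctaSet(mask=mask, objects=tuple(objects), total_area=int(mask.sum()))


def max_intensity_projection(stack: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the slices of a z-stack."""
    arrs = [np.asarray(a) for a in stack]
    if len(arrs) == 0:
        raise ValueError("projection needs at least one slice")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all slices must share one shape")
    return np.max(np.stack(arrs, axis=0), axis=0)


def autophagy_index(puncta: PunctaSet, muscle: MuscleMask) -> float:
    """Total puncta area divided by total muscle area for one field."""
    if muscle.total_area <= 0:
        raise ValueError("zero muscle area: field must be dropped upstream")
    return puncta.total_area / muscle.total_area


def count_puncta(
    section: np.ndarray,
    roi: np.ndarray,
    params: RatsParams | None = None,
    min_size: int = 4,
    connectivity: int = 4,
) -> int:
    """Count puncta in a single confocal section within a region of interest.

    The section is RATS-thresholded, the foreground restricted to ``roi``,
    and connected components (4-connectivity by default; touching objects
    merge into one count) of at least ``min_size`` pixels are counted.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    res = rats_threshold(np.asarray(section, dtype=float), params)
    fg = res.mask & roi
    conn = _skimage_connectivity(connectivity)
    labels = measure.label(fg, connectivity=conn)
    n = 0
    for region in measure.regionprops(labels):
        if region.area >= min_size:
            n += 1
    return n


def manders_overlap(
    chan_a: np.ndarray, chan_b: np.ndarray, roi: np.ndarray | None = None
) -> float:
    """Manders' Overlap Coefficient between two channels over an ROI.

    MOC = sum(A*B) / sqrt(sum(A^2) * sum(B^2)), in [0, 1]; 1 when the
    channels are proportional, 0 when their supports are disjoint.  The
    coefficient is symmetric and invariant under positive rescaling of
    either channel.
    """
    a = np.asarray(chan_a, dtype=np.float64)
    b = np.asarray(chan_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channels must share one shape")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        a, b = a[roi], b[roi]
    sa, sb = float(np.sum(a * a)), float(np.sum(b * b))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("MOC undefined: a channel is identically zero in the ROI")
    return float(np.sum(a * b) / math.sqrt(sa * sb))


def flux_ratio(
    gfp_puncta: PunctaSet, red_puncta: PunctaSet, match_radius: float = 5.0
) -> float:
    """Autophagic-flux readout from a dual (GFP + mCherry) reporter.

    Acidified autolysosomes quench GFP, so puncta visible only in the red
    channel have progressed past the autophagosome stage.  Red puncta are
    matched to GFP puncta by centroid distance; the ratio returned is
    (# red-only puncta) / (# dual red+green puncta).  With no red puncta the
    ratio is 0 (with a warning); with red puncta but no dual ones it is
    ``inf`` (with a warning).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    red = red_puncta.centroids
    if len(red) == 0:
        warnings.warn("no red puncta: flux ratio set to 0", stacklevel=2)
        return 0.0
    green = gfp_puncta.centroids
    if len(green) == 0:
        matched = np.zeros(len(red), dtype=bool)
    else:
        dist, _ = cKDTree(green).query(red, k=1)
        matched = dist <= match_radius
    dual = int(matched.sum())
    red_only = int(len(red) - dual)
    if dual == 0:
        warnings.warn("no dual-labeled puncta: flux ratio is infinite", stacklevel=2)
        return math.inf
    return red_only / dual
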