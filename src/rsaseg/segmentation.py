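"""Dynamic-threshold root/crown segmentation of an isolated tooth.

The chain is: binarize air vs. tooth, label 3-D connected components (one per
tooth), extract the surface as the per-slice 8-neighbourhood edge pixels,
histogram the edge-pixel intensities, and place a personalised threshold at
the first valley after the first peak of that histogram. Edge pixels darker
than the threshold are cementum (root surface); brighter ones are enamel
(crown surface). The threshold is recomputed per tooth: enamel/cementum
intensities vary between patients and between teeth of one patient, so no
global cut works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .errors import DegenerateInputWarning, InputError, NoPeakError, ThresholdFailureError
from .volume import VoxelVolume

#: Components smaller than a 3x3x3 voxel cube are treated as noise specks.
DEFAULT_MIN_COMPONENT_VOXELS = 27

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
# In-plane 8-neighbourhood: neighbours within the same axial slice only.
_STRUCT_INPLANE_8 = np.ones((1, 3, 3), dtype=bool)


@dataclass(frozen=True)
class BinaryMask:
    """Tooth (True) vs. air background (False), same shape as its volume."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        if arr.ndim != 3:
            raise InputError("mask must be 3-D")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class ToothComponent:
    """One 26-connected tooth blob in the binarized volume."""

    component_id: int
    mask: BinaryMask
    voxel_count: int


@dataclass(frozen=True)
class EdgeMap:
    """Surface (edge) pixels of one component: tooth pixels with at least one
    background pixel among their 8 in-plane neighbours (out-of-slice borders
    count as background)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class SurfaceHistogram:
    """256-bin count of edge-pixel intensities (the surface-pixel histogram)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (256,):
            raise InputError("surface histogram must have exactly 256 bins")
        object.__setattr__(self, "counts", arr.astype(np.int64))


@dataclass(frozen=True)
class ThresholdResult:
    """Personalised threshold pair for one tooth.

    ``P`` is the first qualifying peak of the (smoothed) surface histogram —
    the cementum mode. ``X`` is the first local minimum after ``P`` — the
    valley between the cementum and enamel modes, used as the root/crown cut.
    ``smoothed_counts`` is the curve actually searched.
    """

    P: int
    X: int
    smoothed_counts: np.ndarray


@dataclass(frozen=True)
class EdgeLabeling:
    """Partition of a component's edge pixels into root (< X) and crown (>= X)."""

    root_edges: EdgeMap
    crown_edges: EdgeMap


def binarize(volume: VoxelVolume, air_threshold: int | None = None) -> BinaryMask:
    """Separate tooth from air: the non-air part is the tooth.

    A voxel is tooth when its intensity is strictly greater than
    ``air_threshold``. When no threshold is given one is chosen by
    between-class-variance maximisation (Otsu) over the whole-volume
    histogram — isolated teeth scanned in air give a strongly bimodal
    histogram, so the automatic cut is reliable; pass ``air_threshold``
    to override it.
    """
    if air_threshold is None:
        flat = volume.intensities
        if flat.min() == flat.max():
            air_threshold = int(flat.min())  # constant volume; degenerate below
        else:
            air_threshold = int(threshold_otsu(flat))
    elif not 0 <= air_threshold <= 255:
        raise InputError(f"air_threshold must be in [0, 255], got {air_threshold}")
    mask = volume.intensities > air_threshold
    if mask.all() or not mask.any():
        warnings.warn(
            f"degenerate binarization (air_threshold={air_threshold}): "
            f"mask is {'all tooth' if mask.all() else 'all air'}",
            DegenerateInputWarning,
            stacklevel=2,
        )
    return BinaryMask(mask)


def connected_components(
    mask: BinaryMask, min_voxels: int = DEFAULT_MIN_COMPONENT_VOXELS
) -> list[ToothComponent]:
    """Label 26-connected 3-D components; each tooth is one component.

    Components are returned largest first; blobs below ``min_voxels``
    (default 27, a 3x3x3 cube) are dropped as reconstruction noise.
    """
    labels, n = ndimage.label(mask.values, structure=_STRUCT_26)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    order = np.argsort(counts, kind="stable")[::-1]
    components = []
    for rank, idx in enumerate(order, start=1):
        size = int(counts[idx])
        if size < min_voxels:
            break  # sorted descending: everything after is smaller
        components.append(
            ToothComponent(
                component_id=rank,
                mask=BinaryMask(labels == idx + 1),
                voxel_count=size,
            )
        )
    return components


def extract_edges(component: ToothComponent) -> EdgeMap:
    """Surface pixels of a component under the per-slice 8-neighbour rule.

    A component pixel is an edge pixel iff at least one of its 8 neighbours
    *within the same axial slice* is background; pixels on the slice border
    are edges (outside the image counts as background).
    """
    mask = component.mask.values
    interior = ndimage.binary_erosion(mask, structure=_STRUCT_INPLANE_8, border_value=0)
    return EdgeMap(mask & ~interior)


def surface_histogram(volume: VoxelVolume, edges: EdgeMap) -> SurfaceHistogram:
    """Histogram of edge-pixel intensities over the 256 8-bit bins."""
    if edges.values.shape != volume.shape:
        raise InputError("edge map shape does not match volume shape")
    if not edges.values.any():
        warnings.warn("empty edge map: all-zero surface histogram", DegenerateInputWarning, stacklevel=2)
        return SurfaceHistogram(np.zeros(256, dtype=np.int64))
    counts = np.bincount(volume.intensities[edges.values], minlength=256)
    return SurfaceHistogram(counts)


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, reflected at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise InputError(f"smoothing_window must be a positive odd integer, got {window}")
    s = counts.astype(np.float64)
    if window == 1:
        return s
    pad = window // 2
    padded = np.pad(s, pad, mode="reflect")
    return np.convolve(padded, np.full(window, 1.0 / window), mode="valid")


def find_threshold(
    hist: SurfaceHistogram,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.10,
    plateau_tolerance_fraction: float = 0.02,
    min_peak_separation: int = 20,
) -> ThresholdResult:
    """Place the personalised segmentation threshold on a surface histogram.

    The raw counts are smoothed by a centred moving average of width
    ``smoothing_window``. ``P`` is the smallest bin at which the smoothed
    curve has a local maximum with prominence at least
    ``min_prominence_fraction`` of the curve's peak-to-trough range (a
    relative criterion, so shifting all counts by a constant changes
    nothing). ``X`` is the location of the minimum value between the first
    peak and the next qualifying peak (the two-mode structure is the
    method's premise; demanding a second mode is what rules out unimodal
    surfaces). Peaks closer than ``min_peak_separation`` bins are treated
    as one noisily-sampled mode — only the higher survives — since the
    cementum and enamel modes the threshold separates sit tens of gray
    levels apart. Because the valley between well-separated intensity modes is
    a near-flat stretch of (almost) empty bins whose exact minimum is
    noise, ties are resolved as a plateau: starting from the minimal bin
    nearest ``P``, the plateau extends over contiguous bins within
    ``plateau_tolerance_fraction`` of the range above the valley floor, and
    its midpoint bin is reported. The midpoint lands on the analytic valley
    of the mixture rather than hugging either mode. ``smoothing_window=1``
    with ``min_prominence_fraction=0`` searches the raw histogram directly.

    Raises
    ------
    NoPeakError
        Fewer than two local maxima pass the prominence filter (unimodal
        surface: no detectable enamel/cementum contrast).
    ThresholdFailureError
        Two peaks exist but no bin separates them, so no minimum can be
        placed between the modes.
    """
    counts = hist.counts
    if np.count_nonzero(counts) < 2:
        raise NoPeakError("histogram needs at least 2 nonzero bins")
    smoothed = _smooth(counts, smoothing_window)
    span = smoothed.max() - smoothed.min()
    if span <= 0:
        raise NoPeakError("flat histogram: no peaks")
    # find_peaks ignores prominence=0; clamp to a tiny positive value so the
    # "paper-literal" configuration still returns every strict local maximum.
    prominence = max(min_prominence_fraction * span, np.finfo(float).tiny)

    peaks, props = find_peaks(
        smoothed,
        prominence=prominence,
        plateau_size=(1, None),
        distance=max(min_peak_separation, 1),
    )
    if len(peaks) < 2:
        raise NoPeakError(
            f"{len(peaks)} qualifying peak(s); two modes are required "
            "(unimodal surface histogram)"
        )
    P = int(props["left_edges"][0])  # first (smallest-bin) qualifying peak

    # Valley search interval: strictly between the first two peak plateaus.
    lo = int(props["right_edges"][0]) + 1
    hi = int(props["left_edges"][1]) - 1
    if lo > hi:
        raise ThresholdFailureError(f"no bins between the first two peaks (P={P})")
    floor_value = smoothed[lo : hi + 1].min()
    # np.argmin takes the first occurrence: the minimal bin closest to P.
    min_pos = lo + int(np.argmin(smoothed[lo : hi + 1]))
    tied = smoothed <= floor_value + plateau_tolerance_fraction * span
    left = right = min_pos
    while left - 1 >= lo and tied[left - 1]:
        left -= 1
    while right + 1 <= hi and tied[right + 1]:
        right += 1
    X = (left + right) // 2
    return ThresholdResult(P=P, X=X, smoothed_counts=smoothed)


def classify_edges(
    volume: VoxelVolume, edges: EdgeMap, threshold: ThresholdResult | int
) -> EdgeLabeling:
    """Split edge pixels at X: intensity < X is root surface, >= X is crown."""
    x = threshold.X if isinstance(threshold, ThresholdResult) else int(threshold)
    below = volume.intensities < x
    return EdgeLabeling(
        root_edges=EdgeMap(edges.values & below),
        crown_edges=EdgeMap(edges.values & ~below),
    )
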