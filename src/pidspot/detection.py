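"""Bright-spot detection for phosphor-integrated-dot (PID) fluorescence images.

The detector runs in two stages on a high-pass-filtered image:

* Step I — spot identification. The filtered image is scanned with a 3x3
  window; a pixel strictly greater than its 8 neighbours is a local maximum,
  one strictly smaller is a local minimum. Each maximum is paired with its
  nearest minimum, and only maxima whose brightness exceeds that minimum by
  at least the *noise tolerance* (default 32 ADU on the 12-bit scale) are
  kept as positive points. This prominence test separates genuine
  nanoparticle spots from residual noise peaks.

* Step II — spot area definition. The filtered image is binarized at a fixed
  threshold (default 16 ADU) and connected components are extracted. A
  component that contains at least one positive point becomes a bright spot;
  components without one are discarded as autofluorescence residue.

The resulting SpotRecords carry an integrated signal (sum of filtered ADU
over the spot area) and a peak value; either can be fed to a standard curve
to estimate how many particles the spot contains (step III, see
:mod:`pidspot.calibration`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .image_io import Image12

__all__ = [
    "DetectionParams",
    "ExtremumPoint",
    "SpotRecord",
    "Region",
    "high_pass",
    "clamp_nonnegative",
    "find_local_extrema",
    "match_nearest_minimum",
    "apply_noise_tolerance",
    "binarize",
    "label_spot_areas",
    "integrate_spots",
    "detect",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class DetectionParams:
    """Tunable parameters of the spot detector.

    Attributes
    ----------
    noise_tolerance : float
        Minimum brightness difference (ADU) between a local maximum and its
        nearest local minimum for the maximum to count as a real spot.
        Default 32 on the 12-bit scale.
    binarize_threshold : float
        Fixed threshold (ADU) applied to the clamped high-pass image to
        define spot areas. Default 16.
    highpass_sigma : float
        Standard deviation (pixels) of the Gaussian blur subtracted from the
        image; ~ the spot radius. Default 2.0.
    min_search_radius : float
        Cap (pixels) on the nearest-minimum search around each maximum.
        Default 10.
    connectivity : {4, 8}
        Pixel connectivity used when labeling spot areas. Default 8.
    drop_border_regions : bool
        If True, discard spot areas touching the image border.
    """

    noise_tolerance: float = 32.0
    binarize_threshold: float = 16.0
    highpass_sigma: float = 2.0
    min_search_radius: float = 10.0
    connectivity: Literal[4, 8] = 8
    drop_border_regions: bool = False

    def __post_init__(self) -> None:
        if self.noise_tolerance <= 0:
            raise ValueError("noise_tolerance must be > 0")
        if self.binarize_threshold <= 0:
            raise ValueError("binarize_threshold must be > 0")
        if self.highpass_sigma <= 0:
            raise ValueError("highpass_sigma must be > 0")
        if self.min_search_radius <= 0:
            raise ValueError("min_search_radius must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class ExtremumPoint:
    """A strict 8-neighbour local extremum of the filtered image."""

    x: int
    y: int
    value: float
    kind: Literal["maximum", "minimum"]


@dataclass
class SpotRecord:
    """An accepted bright spot.

    ``centroid_x``/``centroid_y`` are intensity-weighted over the spot area
    in the clamped high-pass image; ``integrated_signal`` is the ADU sum over
    that area; ``particle_count`` stays None until a standard curve is
    applied.
    """

    spot_id: int
    centroid_x: float
    centroid_y: float
    area_px: int
    integrated_signal: float
    peak_value: float
    n_positive_maxima: int = 1
    particle_count: Optional[float] = None


@dataclass
class Region:
    """A connected component of the binarized image (its pixel set)."""

    ys: np.ndarray
    xs: np.ndarray
    shape: Tuple[int, int]

    @property
    def area(self) -> int:
        return len(self.ys)

    def touches_border(self) -> bool:
        h, w = self.shape
        return bool(
            (self.ys == 0).any()
            or (self.xs == 0).any()
            or (self.ys == h - 1).any()
            or (self.xs == w - 1).any()
        )


def _as_array(img) -> np.ndarray:
    if isinstance(img, Image12):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def high_pass(img, sigma: float = 2.0) -> np.ndarray:
    """Subtract a Gaussian blur from the image (unsharp high-pass).

    Removes the smooth autofluorescence background while keeping the
    high-frequency nanoparticle spots. The output is signed; callers clamp
    negatives to zero (:func:`clamp_nonnegative`) before extrema scanning and
    binarization so the 12-bit ADU thresholds keep their meaning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    arr = _as_array(img)
    return arr - ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest")


def clamp_nonnegative(filtered: np.ndarray) -> np.ndarray:
    """Clamp negative high-pass values to 0 ADU."""
    return np.clip(filtered, 0.0, None)


def find_local_extrema(
    filtered: np.ndarray,
) -> Tuple[List[ExtremumPoint], List[ExtremumPoint]]:
    """Scan with a 3x3 window for strict local maxima and minima.

    A pixel is a maximum iff strictly greater than all 8 neighbours, a
    minimum iff strictly smaller. Border pixels (incomplete neighbourhood)
    are never extrema, and plateaus yield none: a gradually changing
    brightness distribution produces no extrema at all.
    """
    arr = np.asarray(filtered, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("extrema scan requires a 2D image of at least 3x3 pixels")
    h, w = arr.shape
    c = arr[1:-1, 1:-1]
    is_max = np.ones(c.shape, dtype=bool)
    is_min = np.ones(c.shape, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            nb = arr[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
            is_max &= c > nb
            is_min &= c < nb
    maxima = [
        ExtremumPoint(x=int(x) + 1, y=int(y) + 1, value=float(c[y, x]), kind="maximum")
        for y, x in zip(*np.nonzero(is_max))
    ]
    minima = [
        ExtremumPoint(x=int(x) + 1, y=int(y) + 1, value=float(c[y, x]), kind="minimum")
        for y, x in zip(*np.nonzero(is_min))
    ]
    return maxima, minima


def match_nearest_minimum(
    max_point: ExtremumPoint,
    minima: Sequence[ExtremumPoint],
    max_radius: float = 10.0,
) -> Optional[ExtremumPoint]:
    """Find the nearest local minimum to a maximum, within ``max_radius``.

    Ties in distance are broken by lower value, then smaller y, then smaller
    x. Returns None when no minimum lies within the radius.
    """
    if max_point.kind != "maximum":
        raise ValueError("match_nearest_minimum expects a maximum point")
    r2 = max_radius * max_radius
    best = None
    best_key = None
    for m in minima:
        d2 = (m.x - max_point.x) ** 2 + (m.y - max_point.y) ** 2
        if d2 > r2:
            continue
        key = (d2, m.value, m.y, m.x)
        if best_key is None or key < best_key:
            best_key = key
            best = m
    return best


def apply_noise_tolerance(
    maxima: Sequence[ExtremumPoint],
    minima: Sequence[ExtremumPoint],
    tolerance: float = 32.0,
    max_radius: float = 10.0,
) -> List[ExtremumPoint]:
    """Keep maxima whose prominence over the nearest minimum reaches ``tolerance``.

    A maximum with no minimum within ``max_radius`` is compared against an
    implicit background of 0 ADU: a strong peak in a minimum-free
    neighbourhood is self-evidently prominent. The boundary is inclusive
    (a difference exactly equal to the tolerance is accepted).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not maxima:
        return []
    if not minima:
        return [m for m in maxima if m.value >= tolerance]

    max_xy = np.array([[m.x, m.y] for m in maxima], dtype=np.float64)
    min_xy = np.array([[m.x, m.y] for m in minima], dtype=np.float64)
    from scipy.spatial import cKDTree

    tree = cKDTree(min_xy)
    dist, idx = tree.query(max_xy, k=1, distance_upper_bound=max_radius + 1e-9)

    accepted: List[ExtremumPoint] = []
    for i, mx in enumerate(maxima):
        if not np.isfinite(dist[i]):
            if mx.value >= tolerance:
                accepted.append(mx)
            continue
        # resolve distance ties deterministically (integer grid: ties common)
        matched = match_nearest_minimum(mx, minima, max_radius)
        if matched is None:  # pragma: no cover - kdtree said otherwise
            if mx.value >= tolerance:
                accepted.append(mx)
        elif mx.value - matched.value >= tolerance:
            accepted.append(mx)
    return accepted


def binarize(filtered: np.ndarray, threshold: float = 16.0) -> np.ndarray:
    """Boolean mask of pixels whose clamped high-pass value reaches ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return clamp_nonnegative(np.asarray(filtered, dtype=np.float64)) >= threshold


def label_spot_areas(mask: np.ndarray, connectivity: int = 8) -> List[Region]:
    """Connected components of the binary mask as candidate spot areas."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    regions: List[Region] = []
    if n == 0:
        return regions
    objects = ndimage.find_objects(labels)
    for lbl, sl in enumerate(objects, start=1):
        sub = labels[sl] == lbl
        ys, xs = np.nonzero(sub)
        regions.append(
            Region(
                ys=ys + sl[0].start,
                xs=xs + sl[1].start,
                shape=mask.shape,
            )
        )
    return regions


def integrate_spots(
    positive_points: Sequence[ExtremumPoint],
    regions: Sequence[Region],
    filtered: np.ndarray,
    drop_border_regions: bool = False,
) -> List[SpotRecord]:
    """Combine positive points (step I) with spot areas (step II).

    Only regions containing at least one positive point become spots; a
    region holding several positive maxima is reported as a single spot with
    ``n_positive_maxima`` > 1. Positive points outside every region are
    dropped. Signal is integrated over the region in the clamped high-pass
    image.
    """
    clamped = clamp_nonnegative(np.asarray(filtered, dtype=np.float64))
    if not regions or not positive_points:
        return []
    label_map = np.zeros(clamped.shape, dtype=np.int32)
    for i, reg in enumerate(regions, start=1):
        label_map[reg.ys, reg.xs] = i

    counts: dict[int, int] = {}
    for p in positive_points:
        lbl = int(label_map[p.y, p.x])
        if lbl > 0:
            counts[lbl] = counts.get(lbl, 0) + 1

    spots: List[SpotRecord] = []
    spot_id = 1
    for lbl in sorted(counts):
        reg = regions[lbl - 1]
        if drop_border_regions and reg.touches_border():
            continue
        vals = clamped[reg.ys, reg.xs]
        total = float(vals.sum())
        if total > 0:
            cx = float((reg.xs * vals).sum() / total)
            cy = float((reg.ys * vals).sum() / total)
        else:  # degenerate: unweighted centroid
            cx = float(reg.xs.mean())
            cy = float(reg.ys.mean())
        spots.append(
            SpotRecord(
                spot_id=spot_id,
                centroid_x=cx,
                centroid_y=cy,
                area_px=reg.area,
                integrated_signal=total,
                peak_value=float(vals.max()),
                n_positive_maxima=counts[lbl],
            )
        )
        spot_id += 1
    return spots


def detect(img, params: Optional[DetectionParams] = None) -> List[SpotRecord]:
    """Run the full two-stage detector on a 12-bit image.

    Deterministic composition: high-pass filter, clamp, 3x3 extrema scan,
    noise-tolerance acceptance, binarization, area labeling, and
    point-in-area integration.
    """
    if params is None:
        params = DetectionParams()
    arr = _as_array(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("detection requires an image of at least 3x3 pixels")
    filtered = high_pass(arr, params.highpass_sigma)
    clamped = clamp_nonnegative(filtered)
    maxima, minima = find_local_extrema(clamped)
    positive = apply_noise_tolerance(
        maxima, minima, params.noise_tolerance, params.min_search_radius
    )
    mask = binarize(clamped, params.binarize_threshold)
    regions = label_spot_areas(mask, params.connectivity)
    return integrate_spots(
        positive, regions, clamped, drop_border_regions=params.drop_border_regions
    )
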