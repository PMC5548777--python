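"""Per-area and per-cell particle quantification, and group comparison.

Calibrated spot tables are reduced to the quantities used for reporting:
total particles, particle density per 0.01 mm^2 (the 100 um x 100 um field
convention), and particles per cell. A cell is conventionally a 10 um
square (100 um^2), so a 0.01 mm^2 field holds 100 such cells; users can
instead supply explicit cell ROIs or a cell count.

Group comparison follows the classical two-stage recipe: a two-sided F-test
of variance equality at alpha = 0.05 chooses between Student's pooled
t-test (variances equal) and Welch's t-test (unequal); both are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "QuantResult",
    "GroupComparison",
    "PerCellResult",
    "particle_density",
    "particles_per_cell_from_density",
    "particles_per_cell",
    "compare_groups",
]

CELL_AREA_UM2_DEFAULT = 100.0  # 10 um x 10 um square cell
UM2_PER_001MM2 = 10_000.0  # 0.01 mm^2 expressed in um^2


@dataclass
class QuantResult:
    """Summary quantities for one image/field."""

    n_spots: int
    total_particles: float
    density_per_001mm2: Optional[float] = None
    particles_per_cell: Optional[float] = None
    field_id: str = ""


@dataclass
class PerCellResult:
    per_cell: List[float]
    mean: float
    n_outside: int = 0
    particles_outside: float = 0.0


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    f_stat: float
    f_test_p: float
    variance_equal: bool
    test_used: Literal["student", "welch"]
    t_stat: float
    t_p: float


def _total_particles(spots: Sequence) -> float:
    total = 0.0
    for s in spots:
        if s.particle_count is None:
            raise ValueError(
                f"spot {s.spot_id} has no particle_count; apply a standard curve first"
            )
        total += s.particle_count
    return total


def particle_density(spots: Sequence, image_area_mm2: float) -> float:
    """Total calibrated particles per 0.01 mm^2 of imaged area."""
    if image_area_mm2 is None or image_area_mm2 <= 0:
        raise ValueError("image_area_mm2 must be a positive area in mm^2")
    return _total_particles(spots) / (image_area_mm2 / 0.01)


def particles_per_cell_from_density(
    density_per_001mm2: float, cell_area_um2: float = CELL_AREA_UM2_DEFAULT
) -> float:
    """Convert a per-0.01 mm^2 density to particles per cell.

    With the default 100 um^2 cell (a 10 um square) there are 100 cells per
    0.01 mm^2 field, so a density of 8.8 corresponds to 0.088 ~ 0.09
    particles per cell.
    """
    if cell_area_um2 <= 0:
        raise ValueError("cell_area_um2 must be > 0")
    return density_per_001mm2 * cell_area_um2 / UM2_PER_001MM2


def particles_per_cell(
    spots: Sequence,
    cell_rois: Optional[Sequence] = None,
    cell_count: Optional[int] = None,
) -> PerCellResult:
    """Mean particles per cell, from explicit cell ROIs or a plain cell count.

    ROI mode: each ROI is a 2D boolean mask (or a shapely polygon); spots are
    assigned to the cell whose ROI contains their centroid. Overlapping ROIs
    are rejected as ambiguous. Spots outside every ROI are reported, not
    silently dropped. Count mode: total particles divided by ``cell_count``.
    """
    if (cell_rois is None) == (cell_count is None):
        raise ValueError("provide exactly one of cell_rois or cell_count")

    if cell_count is not None:
        if cell_count < 1:
            raise ValueError("cell_count must be >= 1")
        total = _total_particles(spots)
        return PerCellResult(per_cell=[], mean=total / cell_count)

    rois = list(cell_rois)
    if not rois:
        raise ValueError("cell_rois is empty")
    is_mask = hasattr(rois[0], "ndim")
    if is_mask:
        masks = [np.asarray(r, dtype=bool) for r in rois]
        stacked = np.sum(masks, axis=0)
        if (stacked > 1).any():
            raise ValueError("cell ROIs overlap; spot-to-cell assignment is ambiguous")
    else:
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                inter = rois[i].intersection(rois[j])
                if getattr(inter, "area", 0) > 0:
                    raise ValueError(
                        "cell ROIs overlap; spot-to-cell assignment is ambiguous"
                    )

    per_cell = [0.0] * len(rois)
    n_outside = 0
    particles_outside = 0.0
    for s in spots:
        if s.particle_count is None:
            raise ValueError(
                f"spot {s.spot_id} has no particle_count; apply a standard curve first"
            )
        assigned = False
        for i, roi in enumerate(rois):
            if is_mask:
                yy = int(round(s.centroid_y))
                xx = int(round(s.centroid_x))
                h, w = roi.shape
                inside = 0 <= yy < h and 0 <= xx < w and roi[yy, xx]
            else:
                from shapely.geometry import Point

                inside = roi.covers(Point(s.centroid_x, s.centroid_y))
            if inside:
                per_cell[i] += s.particle_count
                assigned = True
                break
        if not assigned:
            n_outside += 1
            particles_outside += s.particle_count
    return PerCellResult(
        per_cell=per_cell,
        mean=float(np.mean(per_cell)),
        n_outside=n_outside,
        particles_outside=particles_outside,
    )


def compare_groups(scores_a: Sequence[float], scores_b: Sequence[float]) -> GroupComparison:
    """F-test-gated two-sided t-test between two groups.

    The variance-equality F-test puts the larger sample variance in the
    numerator and doubles the one-tailed probability (two-sided, the common
    convention). If its p >= 0.05 the groups are treated as equal-variance
    and compared with Student's pooled t-test; otherwise with Welch's t-test
    using the Welch-Satterthwaite degrees of freedom. All statistics are
    computed from first principles against the F and t distributions.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    # two-sided F-test: larger variance in the numerator
    if va >= vb:
        f_stat = va / vb if vb > 0 else np.inf
        dfn, dfd = na - 1, nb - 1
    else:
        f_stat = vb / va if va > 0 else np.inf
        dfn, dfd = nb - 1, na - 1
    if np.isinf(f_stat):
        f_p = 0.0
    else:
        f_p = float(min(1.0, 2.0 * stats.f.sf(f_stat, dfn, dfd)))
    variance_equal = f_p >= 0.05

    if variance_equal:
        test_used = "student"
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        test_used = "welch"
        se2a, se2b = va / na, vb / nb
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (na - 1) + se2b**2 / (nb - 1)
        )

    if se == 0:
        t_stat = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        t_p = 1.0 if mean_a == mean_b else 0.0
    else:
        t_stat = (mean_a - mean_b) / se
        t_p = float(min(1.0, 2.0 * stats.t.sf(abs(t_stat), df)))

    return GroupComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        f_stat=float(f_stat),
        f_test_p=f_p,
        variance_equal=variance_equal,
        test_used=test_used,
        t_stat=float(t_stat),
        t_p=t_p,
    )
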