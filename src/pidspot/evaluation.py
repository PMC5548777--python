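"""Detection scoring against ground truth, and correlation metrics.

Detections are matched one-to-one to true spot positions greedily in order
of increasing distance, with a matching radius (default 3 px, about one PSF
diameter); precision, recall and the F-measure summarise the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MatchResult", "match_detections", "f_measure", "pearson_r"]


@dataclass
class MatchResult:
    """One-to-one matching between detected and true spot positions."""

    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[int, int]] = field(default_factory=list)  # (det_idx, truth_idx)
    radius_px: float = 3.0


def _as_points(pts) -> np.ndarray:
    if len(pts) == 0:
        return np.zeros((0, 2), dtype=np.float64)
    first = pts[0]
    if hasattr(first, "centroid_x"):
        return np.array([[p.centroid_x, p.centroid_y] for p in pts], dtype=np.float64)
    return np.asarray(pts, dtype=np.float64).reshape(len(pts), 2)


def match_detections(
    detected, truth, radius_px: float = 3.0
) -> MatchResult:
    """Greedily match detections to truth in increasing-distance order.

    Accepts (x, y) sequences or SpotRecord lists. Each detection and each
    truth point is used at most once; candidate pairs farther apart than
    ``radius_px`` never match. Distance ties are resolved by detection then
    truth index, so the matching is deterministic.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    det = _as_points(detected)
    tru = _as_points(truth)
    nd, nt = len(det), len(tru)
    pairs: List[Tuple[int, int]] = []
    if nd and nt:
        d2 = ((det[:, None, :] - tru[None, :, :]) ** 2).sum(axis=2)
        cand = np.argwhere(d2 <= radius_px**2)
        order = sorted(
            (float(d2[i, j]), int(i), int(j)) for i, j in cand
        )
        used_d: set[int] = set()
        used_t: set[int] = set()
        for _, i, j in order:
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=nd - tp, fn=nt - tp, pairs=pairs, radius_px=radius_px)


def f_measure(match: MatchResult) -> Tuple[float, float, float]:
    """(precision, recall, F) of a match result.

    F is the harmonic mean of precision and recall, 0 when both are 0.
    Undefined (rejected) when there are neither detections nor truths.
    """
    n_det = match.tp + match.fp
    n_tru = match.tp + match.fn
    if n_det == 0 and n_tru == 0:
        raise ValueError("F-measure undefined with no detections and no ground truth")
    precision = match.tp / n_det if n_det else 0.0
    recall = match.tp / n_tru if n_tru else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(xa, ya)[0, 1])
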