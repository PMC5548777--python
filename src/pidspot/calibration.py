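"""Standard-curve calibration: spot fluorescence signal -> particle number.

In the reference workflow the curve is built from bright spots imaged by
both fluorescence microscopy and scanning electron microscopy: the SEM image
gives the true particle number in each spot, the fluorescence image its
signal, and an ordinary least-squares line through the paired observations
maps signal to count. Here the pairs arrive as a plain table; fitting and
inversion are exact arithmetic.

Per-spot counts are kept continuous (not rounded): reported quantities are
means over areas or cells, where fractional values are meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationPair",
    "StandardCurve",
    "fit_standard_curve",
    "signal_to_count",
    "calibrate_spots",
    "read_calibration_pairs",
    "write_calibration_pairs",
]


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration observation: spot signal (ADU) and true particle count."""

    signal: float
    count: float

    def __post_init__(self) -> None:
        if self.signal <= 0:
            raise ValueError("calibration signal must be > 0")
        if self.count < 1:
            raise ValueError("calibration count must be >= 1")


@dataclass
class StandardCurve:
    """Fitted line ``count = slope * signal + intercept``.

    ``r`` is the Pearson correlation of the fitting data; ``signal_kind``
    records which spot-signal variant the curve expects (integrated sum over
    the spot area, or peak pixel value).
    """

    slope: float
    intercept: float
    r: float
    n: int
    signal_kind: Literal["integrated", "peak"] = "integrated"

    @property
    def is_valid(self) -> bool:
        return self.n >= 3 and self.slope > 0 and abs(self.r) <= 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r": self.r,
                    "n": self.n,
                    "signal_kind": self.signal_kind,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r=d["r"],
            n=d["n"],
            signal_kind=d.get("signal_kind", "integrated"),
        )


def fit_standard_curve(
    pairs: Sequence[CalibrationPair],
    through_origin: bool = False,
    signal_kind: Literal["integrated", "peak"] = "integrated",
) -> StandardCurve:
    """Least-squares fit of ``count = slope * signal (+ intercept)``.

    With ``through_origin`` the intercept is constrained to zero. The
    reported ``r`` is always the Pearson correlation of the raw pairs. A
    non-positive fitted slope triggers a warning — such a curve cannot be
    inverted into particle counts.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 calibration pairs, got {n}")
    sig = np.array([p.signal for p in pairs], dtype=np.float64)
    cnt = np.array([p.count for p in pairs], dtype=np.float64)
    if np.ptp(sig) == 0:
        raise ValueError("calibration signals are all equal; cannot fit a curve")

    if through_origin:
        slope = float(sig.dot(cnt) / sig.dot(sig))
        intercept = 0.0
    else:
        A = np.column_stack([sig, np.ones_like(sig)])
        coef, *_ = np.linalg.lstsq(A, cnt, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])

    if np.ptp(cnt) == 0:
        r = 0.0
        slope = 0.0  # counts carry no signal dependence; lstsq noise is not a slope
        intercept = float(cnt[0])
    else:
        r = float(np.corrcoef(sig, cnt)[0, 1])

    if slope <= 0:
        warnings.warn(
            f"standard curve has non-positive slope ({slope:.4g}); "
            "the fit is not usable for particle counting",
            UserWarning,
            stacklevel=2,
        )
    return StandardCurve(slope=slope, intercept=intercept, r=r, n=n, signal_kind=signal_kind)


def signal_to_count(curve: StandardCurve, signal) -> float | np.ndarray:
    """Convert spot signal (ADU) to a continuous particle count, clamped at 0."""
    if not curve.is_valid:
        raise ValueError("standard curve is invalid (need n >= 3 and slope > 0)")
    out = np.maximum(0.0, curve.slope * np.asarray(signal, dtype=np.float64) + curve.intercept)
    if np.isscalar(signal) or np.ndim(signal) == 0:
        return float(out)
    return out


def calibrate_spots(spots: Sequence, curve: StandardCurve) -> List:
    """Fill ``particle_count`` for every spot using the curve's signal kind."""
    field = "integrated_signal" if curve.signal_kind == "integrated" else "peak_value"
    out = []
    for s in spots:
        if not hasattr(s, field):
            raise ValueError(f"spot record lacks the '{field}' signal field")
        out.append(replace(s, particle_count=signal_to_count(curve, getattr(s, field))))
    return out


def write_calibration_pairs(pairs: Sequence[CalibrationPair], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"signal": [p.signal for p in pairs], "count": [p.count for p in pairs]}
    ).to_csv(path, index=False)


def read_calibration_pairs(path: str | Path) -> List[CalibrationPair]:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("signal", "count"):
        if col not in df.columns:
            raise ValueError(f"malformed calibration table {path}: missing column '{col}'")
    return [CalibrationPair(float(s), float(c)) for s, c in zip(df["signal"], df["count"])]
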