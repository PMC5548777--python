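"""Image and table I/O on the 12-bit brightness scale.

All downstream thresholds (noise tolerance 32 ADU, binarization threshold
16 ADU) are defined on a 12-bit scale, so every image entering the pipeline
is normalized to integer ADU values in [0, 4095] at load time. 12-bit camera
data is conventionally stored in 16-bit TIFF containers; the loader
auto-detects this by the maximum pixel value, with an explicit override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_ADU = 4095  # full scale of a 12-bit analog-to-digital converter

SPOT_TABLE_COLUMNS = [
    "spot_id",
    "centroid_x",
    "centroid_y",
    "area_px",
    "integrated_signal",
    "peak_value",
    "particle_count",
]


@dataclass
class Image12:
    """A single-channel image on the 12-bit ADU scale [0, 4095].

    Parameters
    ----------
    pixels : ndarray
        2D integer array of brightness values in ADU.
    pixel_size_um : float, optional
        Physical pixel size in micrometres. Required only for area-based
        quantification (particles per mm^2).

    Coordinates are 0-based with ``x`` the column index and ``y`` the row
    index; pixel centers sit at integer coordinates.
    """

    pixels: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError(
                f"Image12 requires a 2D single-channel array, got {pix.ndim} dimensions"
            )
        if pix.size and (pix.min() < 0 or pix.max() > MAX_ADU):
            raise ValueError(
                f"pixel values must lie in [0, {MAX_ADU}]; "
                f"got range [{pix.min()}, {pix.max()}]"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = pix.astype(np.uint16)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        """Field area in mm^2 (requires pixel_size_um)."""
        if self.pixel_size_um is None:
            raise ValueError("pixel_size_um is not set; cannot compute field area")
        return self.height * self.width * (self.pixel_size_um * 1e-3) ** 2


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)))


def load_image(
    path: str | Path,
    bit_depth_hint: Optional[int] = None,
    pixel_size_um: Optional[float] = None,
) -> Image12:
    """Load a grayscale TIFF/PNG and normalize it to the 12-bit scale.

    Mapping rules:

    * 8-bit input: values multiplied by 16 (255 -> 4080).
    * 16-bit container, max value <= 4095 (or ``bit_depth_hint=12``): values
      pass through unchanged, assumed to be 12-bit data.
    * 16-bit container with larger values (or ``bit_depth_hint=16``): values
      right-shifted by 4 bits (65535 -> 4095).

    The mapping applied is logged, since the container depth of 12-bit
    camera data is a convention rather than something the file declares.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    raw = _read_raster(path)
    if raw.ndim == 3:
        raise ValueError(
            f"expected a single-channel grayscale image, got {raw.shape[-1]} channels"
        )
    if raw.ndim != 2:
        raise ValueError(f"expected a 2D image, got {raw.ndim} dimensions")
    if np.issubdtype(raw.dtype, np.floating):
        raise ValueError("floating-point images are not supported; provide integer ADU data")

    maxval = int(raw.max()) if raw.size else 0
    if raw.dtype == np.uint8 or (bit_depth_hint == 8):
        if maxval > 255:
            raise ValueError(f"values exceed declared 8-bit depth (max {maxval})")
        pixels = raw.astype(np.uint16) * 16
        logger.info("load_image(%s): 8-bit input scaled x16 onto 12-bit scale", path.name)
    elif bit_depth_hint == 12:
        if maxval > MAX_ADU:
            raise ValueError(f"values exceed declared 12-bit depth (max {maxval})")
        pixels = raw.astype(np.uint16)
        logger.info("load_image(%s): declared 12-bit data, passed through", path.name)
    elif bit_depth_hint == 16:
        pixels = (raw.astype(np.uint32) >> 4).astype(np.uint16)
        logger.info("load_image(%s): declared 16-bit data, right-shifted 4 bits", path.name)
    elif bit_depth_hint is None:
        if maxval <= MAX_ADU:
            pixels = raw.astype(np.uint16)
            logger.info(
                "load_image(%s): max %d <= 4095, assumed 12-bit data in 16-bit container",
                path.name,
                maxval,
            )
        else:
            pixels = (raw.astype(np.uint32) >> 4).astype(np.uint16)
            logger.info(
                "load_image(%s): max %d > 4095, assumed native 16-bit, right-shifted 4 bits",
                path.name,
                maxval,
            )
    else:
        raise ValueError(f"unsupported bit_depth_hint: {bit_depth_hint}")
    return Image12(pixels, pixel_size_um=pixel_size_um)


def save_image(img: Image12, path: str | Path) -> None:
    """Write an Image12 as a 16-bit grayscale TIFF (values stay on [0, 4095])."""
    import tifffile

    tifffile.imwrite(str(path), img.pixels.astype(np.uint16))


def write_spot_table(spots, path: str | Path) -> None:
    """Write SpotRecords to CSV.

    Centroids are written to 2 decimals, signals to 1 decimal;
    ``particle_count`` is left blank until calibration fills it.
    """
    rows = []
    for s in spots:
        rows.append(
            {
                "spot_id": s.spot_id,
                "centroid_x": round(s.centroid_x, 2),
                "centroid_y": round(s.centroid_y, 2),
                "area_px": s.area_px,
                "integrated_signal": round(s.integrated_signal, 1),
                "peak_value": round(s.peak_value, 1),
                "particle_count": (
                    "" if s.particle_count is None else round(s.particle_count, 4)
                ),
                "n_positive_maxima": s.n_positive_maxima,
            }
        )
    df = pd.DataFrame(rows, columns=SPOT_TABLE_COLUMNS + ["n_positive_maxima"])
    df.to_csv(path, index=False)


def read_spot_table(path: str | Path):
    """Read a spot-table CSV back into SpotRecords (inverse of write_spot_table)."""
    from .detection import SpotRecord

    df = pd.read_csv(path)
    missing = [c for c in SPOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed spot table {path}: missing column(s) {missing}")
    spots = []
    for _, row in df.iterrows():
        count = row["particle_count"]
        spots.append(
            SpotRecord(
                spot_id=int(row["spot_id"]),
                centroid_x=float(row["centroid_x"]),
                centroid_y=float(row["centroid_y"]),
                area_px=int(row["area_px"]),
                integrated_signal=float(row["integrated_signal"]),
                peak_value=float(row["peak_value"]),
                n_positive_maxima=(
                    int(row["n_positive_maxima"]) if "n_positive_maxima" in df.columns else 1
                ),
                particle_count=None if pd.isna(count) else float(count),
            )
        )
    return spots
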