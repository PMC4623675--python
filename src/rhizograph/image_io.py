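"""Scan image input, unit conversion and trait-table output.

Conventions used throughout the package:

* intensities are floats in ``[0, 1]``;
* the foreground (roots) is DARKER than the background — images that
  arrive light-on-dark are inverted on load;
* pixel coordinates are 0-based ``(row, col)`` with row 0 at the top.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ConfigurationError, InputError

MM_PER_INCH = 25.4

#: ITU-R 601/709-style luminance weights (as used by skimage.color.rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class ScanImage:
    """A grayscale root scan with physical resolution metadata.

    ``pixels`` is a 2-D float array in [0, 1]; ``dpi`` converts pixel
    measures to millimetres (mm = px * 25.4 / dpi).
    """

    pixels: np.ndarray
    dpi: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("scan raster must be 2-dimensional and non-empty")
        if not self.dpi > 0:
            raise InputError(f"dpi must be positive, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def px_to_mm(length_px: float, dpi: float) -> float:
    """Convert a pixel length to millimetres: ``px * 25.4 / dpi``."""
    if not dpi > 0:
        raise InputError(f"dpi must be positive, got {dpi}")
    return float(length_px) * MM_PER_INCH / float(dpi)


def _read_raster_and_dpi(path: str) -> tuple[np.ndarray, float | None]:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            dpi = None
            tags = page.tags
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
                unit = getattr(unit, "value", unit)  # enum -> int
                if den and num:
                    res = num / den
                    if unit == 3:  # centimetre
                        res *= 2.54
                    if res > 1:  # a 1/1 placeholder is not a real resolution
                        dpi = float(res)
        return arr, dpi
    # PNG (and anything else Pillow handles)
    with Image.open(path) as im:
        dpi_info = im.info.get("dpi")
        arr = np.asarray(im)
    dpi = None
    if dpi_info:
        d = float(dpi_info[0])
        if d > 1:
            dpi = d
    return arr, dpi


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Grayscale-by-luminance, scale to [0,1], make roots the dark class."""
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].astype(float) @ _LUMA
        if arr.max() > 1.0:
            arr = arr / 255.0
    else:
        arr = arr.astype(float)
        if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() <= 1.0:
            pass
        else:
            info_max = arr.max()
            # scale by the dtype range of common scanner bit depths
            for full in (255.0, 1023.0, 4095.0, 65535.0):
                if info_max <= full:
                    arr = arr / full
                    break
            else:
                arr = arr / info_max
    arr = np.clip(arr, 0.0, 1.0)
    # polarity: background is the majority class -> its median should be
    # light; a dark median means light-on-dark input, so invert once.
    if np.median(arr) < 0.5:
        arr = 1.0 - arr
    return arr


def load_scan(path: str, dpi_override: float | None = None) -> ScanImage:
    """Read a TIFF or PNG root scan.

    Resolution metadata embedded in the file is used unless
    ``dpi_override`` is given; if neither is available a
    :class:`ConfigurationError` is raised (silent defaults would corrupt
    every physical trait downstream).
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        arr, dpi = _read_raster_and_dpi(path)
    except (OSError, ValueError, KeyError) as exc:
        raise InputError(f"unreadable image {path}: {exc}") from exc
    if dpi_override is not None:
        if not dpi_override > 0:
            raise InputError("dpi_override must be positive")
        dpi = float(dpi_override)
    if dpi is None:
        raise ConfigurationError(
            f"{path}: missing required field 'dpi' (no resolution metadata "
            "in file; pass dpi_override)"
        )
    return ScanImage(pixels=_normalize(arr), dpi=dpi, source_path=path)


# ---------------------------------------------------------------------------
# trait table output
# ---------------------------------------------------------------------------

#: CSV column order; units are embedded in the names so the header is
#: self-describing.
TRAIT_COLUMNS = [
    "root_id",
    "length_mm",
    "mean_diameter_mm",
    "min_diameter_mm",
    "max_diameter_mm",
    "surface_area_mm2",
    "volume_mm3",
    "lateral_count",
    "total_lateral_length_mm",
    "laterals_per_cm",
]


def write_traits(report: "pd.DataFrame | object", path: str) -> None:
    """Write a trait report as CSV: one row per primary root plus a
    per-plant ``TOTAL`` summary row.

    Accepts either the :class:`~rhizograph.traits.TraitReport` container
    or a bare per-primary DataFrame with :data:`TRAIT_COLUMNS`.
    """
    df = getattr(report, "per_primary", report)
    if not isinstance(df, pd.DataFrame):
        raise InputError("report must be a TraitReport or DataFrame")
    df = df.reindex(columns=TRAIT_COLUMNS)
    out = df.copy()
    if len(df):
        total = {
            "root_id": "TOTAL",
            "length_mm": df["length_mm"].sum(),
            "mean_diameter_mm": df["mean_diameter_mm"].mean(),
            "min_diameter_mm": df["min_diameter_mm"].min(),
            "max_diameter_mm": df["max_diameter_mm"].max(),
            "surface_area_mm2": df["surface_area_mm2"].sum(),
            "volume_mm3": df["volume_mm3"].sum(),
            "lateral_count": df["lateral_count"].sum(),
            "total_lateral_length_mm": df["total_lateral_length_mm"].sum(),
            "laterals_per_cm": (
                df["lateral_count"].sum() / (df["length_mm"].sum() / 10.0)
                if df["length_mm"].sum() > 0
                else 0.0
            ),
        }
        out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write trait table to {path}: {exc}") from exc


def read_traits(path: str) -> pd.DataFrame:
    """Read back a trait CSV (per-primary rows only, summary row dropped)."""
    df = pd.read_csv(path)
    return df[df["root_id"] != "TOTAL"].reset_index(drop=True)


def write_overlay(
    image: ScanImage,
    primary_pixels: list[np.ndarray],
    lateral_pixels: np.ndarray | None,
    path: str,
) -> None:
    """Save a diagnostic RGB overlay: each primary root in a distinct
    colour, laterals in a common contrasting colour, over the scan."""
    base = (np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    palette = [
        (220, 40, 40), (40, 110, 220), (30, 160, 60), (200, 140, 20),
        (150, 50, 190), (0, 170, 170), (230, 90, 160), (120, 120, 30),
    ]
    if lateral_pixels is not None and len(lateral_pixels):
        r, c = np.asarray(lateral_pixels).T
        rgb[r, c] = (250, 210, 50)
    for i, pix in enumerate(primary_pixels):
        if len(pix) == 0:
            continue
        r, c = np.asarray(pix).T
        rgb[r, c] = palette[i % len(palette)]
    Image.fromarray(rgb).save(path)
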