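"""Spot densitometry on membrane images.

Measures background-corrected integral intensities of spots arranged on a
grayscale raster, given a layout table naming each spot's role (sample
replicate, calibration standard, or background), nominal position and radius.

The local background for each spot is estimated as the median of an annulus
around the spot footprint (robust to bleed from neighbouring spots); the
integral is the sum of in-disk pixel values minus the disk area times that
background.  Partial pixels at the disk edge are included by a
center-in-disk test (no anti-aliased weighting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MembraneImage",
    "SpotLayout",
    "SpotMeasurement",
    "LayoutError",
    "locate_spots",
    "integrate_spot",
    "measure_membrane",
    "LAYOUT_COLUMNS",
    "ROLES",
    "DEFAULT_ANNULUS_OFFSETS",
]

#: Required columns of a layout table / CSV.
LAYOUT_COLUMNS = ("spot_id", "role", "sample_id", "row", "col", "radius", "known_content")

ROLES = frozenset({"sample_replicate", "calibration", "background"})

#: Annulus radii relative to the spot radius: (radius + 2, radius + 6).
DEFAULT_ANNULUS_OFFSETS = (2.0, 6.0)

#: Fraction of in-disk pixels at raster maximum that triggers the saturated flag.
SATURATION_FRACTION = 0.01


class LayoutError(ValueError):
    """Raised for malformed spot layouts."""


@dataclass
class MembraneImage:
    """A 2-D grayscale membrane raster.

    Parameters
    ----------
    pixels:
        2-D array of nonnegative intensities.  Stored as float64 internally;
        simulated membranes are exact (unquantized) unless saved to an
        integer format.
    bit_depth:
        8 or 16 when the raster originates from (or is destined for) an
        integer image; ``None`` for exact synthetic rasters.  Saturation
        detection requires a bit depth.
    """

    pixels: np.ndarray
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be nonnegative")
        if self.bit_depth is not None:
            if self.bit_depth not in (8, 16):
                raise ValueError("bit_depth must be 8, 16 or None")
            if np.any(self.pixels > self.raster_max):
                raise ValueError("pixel values exceed 2**bit_depth - 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def raster_max(self) -> float | None:
        if self.bit_depth is None:
            return None
        return float(2**self.bit_depth - 1)

    def quantized(self, bit_depth: int = 16) -> "MembraneImage":
        """Round and clip to an integer raster of the given bit depth."""
        top = 2**bit_depth - 1
        q = np.clip(np.rint(self.pixels), 0, top)
        return MembraneImage(q, bit_depth=bit_depth)

    def save(self, path: str | Path, bit_depth: int | None = None) -> None:
        """Write as 16-bit (or 8-bit) grayscale TIFF or PNG.

        Float rasters are rounded and clipped; the on-disk image is always
        integer.
        """
        path = Path(path)
        depth = bit_depth or self.bit_depth or 16
        top = 2**depth - 1
        arr = np.clip(np.rint(self.pixels), 0, top)
        arr = arr.astype(np.uint8 if depth == 8 else np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, arr)
        elif path.suffix.lower() == ".png":
            import imageio.v3 as iio

            iio.imwrite(path, arr)
        else:
            raise ValueError(f"unsupported image format: {path.suffix!r}")

    @classmethod
    def load(cls, path: str | Path) -> "MembraneImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        elif path.suffix.lower() == ".png":
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise ValueError(f"unsupported image format: {path.suffix!r}")
        arr = np.asarray(arr)
        if arr.ndim == 3:  # grayscale stored with a channel axis
            arr = arr[..., 0]
        depth = 8 if arr.dtype.itemsize == 1 else 16
        return cls(arr.astype(np.float64), bit_depth=depth)


@dataclass
class SpotLayout:
    """The grid of spot roles, positions and known standard contents.

    Wraps a :class:`pandas.DataFrame` with columns
    ``spot_id, role, sample_id, row, col, radius, known_content``.
    ``row``/``col`` are 0-based pixel coordinates (row-major, origin
    top-left); ``known_content`` is in pg/ng and only set for calibration
    spots.
    """

    spots: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.spots).copy()
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise LayoutError(f"layout is missing columns: {missing}")
        extras = [c for c in df.columns if c not in LAYOUT_COLUMNS]
        df = df.loc[:, list(LAYOUT_COLUMNS) + extras].reset_index(drop=True)
        bad_roles = set(df["role"]) - ROLES
        if bad_roles:
            raise LayoutError(f"unknown spot roles: {sorted(bad_roles)}")
        if df["spot_id"].duplicated().any():
            raise LayoutError("duplicate spot ids")
        if (df["radius"] <= 0).any():
            raise LayoutError("spot radii must be positive")
        cal = df[df["role"] == "calibration"]
        if len(cal):
            contents = cal["known_content"].to_numpy(dtype=float)
            if np.any(~np.isfinite(contents)) or np.any(contents <= 0):
                raise LayoutError("calibration contents must be positive")
            if len(cal) >= 2 and np.unique(contents).size == 1:
                raise LayoutError("calibration contents must not all be equal")
        self.spots = df

    def __len__(self) -> int:
        return len(self.spots)

    def subset(self, role: str) -> pd.DataFrame:
        return self.spots[self.spots["role"] == role]

    @property
    def calibration(self) -> pd.DataFrame:
        return self.subset("calibration")

    @property
    def background(self) -> pd.DataFrame:
        return self.subset("background")

    @property
    def sample_replicates(self) -> pd.DataFrame:
        return self.subset("sample_replicate")

    def to_csv(self, path: str | Path) -> None:
        self.spots.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpotLayout":
        return cls(pd.read_csv(path))


@dataclass
class SpotMeasurement:
    """Background-corrected integral intensity of a single spot."""

    spot_id: object
    refined_center: tuple[float, float]
    integral_intensity: float
    local_background: float
    flags: dict[str, bool] = field(
        default_factory=lambda: {"saturated": False, "low_signal": False, "off_grid": False}
    )

    def to_dict(self) -> dict:
        d = {
            "spot_id": self.spot_id,
            "center_row": self.refined_center[0],
            "center_col": self.refined_center[1],
            "integral_intensity": self.integral_intensity,
            "local_background": self.local_background,
        }
        d.update(self.flags)
        return d


def _distance_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    return np.hypot(rows - center[0], cols - center[1])


def integrate_spot(
    image: MembraneImage,
    center: tuple[float, float],
    radius: float,
    annulus: tuple[float, float] | None = None,
) -> SpotMeasurement:
    """Integrate one spot: sum of in-disk pixels minus area x annulus median.

    Parameters
    ----------
    center:
        (row, col) in pixels; may be fractional (refined centroid).
    radius:
        disk radius in pixels; a pixel belongs to the disk when its center is
        within ``radius`` of ``center``.
    annulus:
        (inner, outer) radii of the local-background annulus.  Defaults to
        ``(radius + 2, radius + 6)``.  The inner radius must be >= radius and
        the annulus must fit inside the image.

    Returns
    -------
    SpotMeasurement
        ``integral_intensity`` may be negative, in which case the
        ``low_signal`` flag is set.  ``saturated`` is set when more than 1%
        of in-disk pixels sit at the raster maximum (integer rasters only).
    """
    if annulus is None:
        annulus = (radius + DEFAULT_ANNULUS_OFFSETS[0], radius + DEFAULT_ANNULUS_OFFSETS[1])
    inner, outer = annulus
    if inner < radius:
        raise ValueError(f"annulus inner radius {inner} must be >= spot radius {radius}")
    if outer <= inner:
        raise ValueError("annulus outer radius must exceed inner radius")
    h, w = image.shape
    r0, c0 = center
    if r0 - outer < -0.5 or c0 - outer < -0.5 or r0 + outer > h - 0.5 or c0 + outer > w - 0.5:
        raise ValueError("annulus extends beyond the image")

    dist = _distance_grid(image.shape, center)
    disk = dist <= radius
    ring = (dist >= inner) & (dist <= outer)
    if not np.any(ring):
        raise ValueError("empty annulus")
    n_disk = int(np.count_nonzero(disk))
    if n_disk == 0:
        raise ValueError("empty disk (radius too small)")

    background = float(np.median(image.pixels[ring]))
    integral = float(image.pixels[disk].sum() - n_disk * background)

    flags = {"saturated": False, "low_signal": integral < 0, "off_grid": False}
    if image.raster_max is not None:
        frac_sat = np.count_nonzero(image.pixels[disk] >= image.raster_max) / n_disk
        flags["saturated"] = frac_sat > SATURATION_FRACTION
    return SpotMeasurement(
        spot_id=None,
        refined_center=(float(r0), float(c0)),
        integral_intensity=integral,
        local_background=background,
        flags=flags,
    )


def locate_spots(
    image: MembraneImage,
    layout: SpotLayout,
    search_window: int = 5,
    low_signal_threshold: float = 0.0,
) -> SpotLayout:
    """Refine nominal spot centers by intensity-weighted centroiding.

    Each spot center is replaced by the centroid of ``pixel - min(window)``
    within a ``(2w+1)``-square window around the nominal center.  Spots whose
    background-corrected window total (window sum minus window area times
    the image median) does not exceed ``low_signal_threshold`` keep their
    nominal center and gain a ``low_signal`` column flag.  Spots whose
    centroid lands near the window edge gain ``off_grid``.
    """
    if search_window < 1:
        raise ValueError("search_window must be >= 1 pixel")
    h, w = image.shape
    global_median = float(np.median(image.pixels))
    rows_out, cols_out, low, off = [], [], [], []
    for _, spot in layout.spots.iterrows():
        r = int(round(spot["row"]))
        c = int(round(spot["col"]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"nominal center of spot {spot['spot_id']!r} outside image")
        r_lo, r_hi = r - search_window, r + search_window
        c_lo, c_hi = c - search_window, c + search_window
        if r_lo < 0 or c_lo < 0 or r_hi >= h or c_hi >= w:
            raise ValueError(f"search window of spot {spot['spot_id']!r} extends beyond image")
        window = image.pixels[r_lo : r_hi + 1, c_lo : c_hi + 1]
        corrected_total = float(window.sum() - window.size * global_median)
        if corrected_total <= low_signal_threshold:
            rows_out.append(float(spot["row"]))
            cols_out.append(float(spot["col"]))
            low.append(True)
            off.append(False)
            continue
        weights = np.clip(window - window.min(), 0, None)
        total = weights.sum()
        if total <= 0:  # perfectly flat window
            rows_out.append(float(spot["row"]))
            cols_out.append(float(spot["col"]))
            low.append(True)
            off.append(False)
            continue
        rr = np.arange(r_lo, r_hi + 1, dtype=np.float64)[:, None]
        cc = np.arange(c_lo, c_hi + 1, dtype=np.float64)[None, :]
        cr = float((weights * rr).sum() / total)
        ccol = float((weights * cc).sum() / total)
        shift = math.hypot(cr - spot["row"], ccol - spot["col"])
        rows_out.append(cr)
        cols_out.append(ccol)
        low.append(False)
        off.append(shift > 0.75 * search_window)
    refined = layout.spots.copy()
    refined["row"] = rows_out
    refined["col"] = cols_out
    refined["low_signal"] = low
    refined["off_grid"] = off
    return SpotLayout(refined)


def measure_membrane(
    image: MembraneImage,
    layout: SpotLayout,
    annulus_offsets: tuple[float, float] = DEFAULT_ANNULUS_OFFSETS,
    refine: bool = False,
    search_window: int = 5,
) -> pd.DataFrame:
    """Measure every spot in the layout; background spots are measured
    identically to the others.

    Returns a MeasurementTable: one row per layout spot with columns
    ``spot_id, role, sample_id, known_content, center_row, center_col,
    integral_intensity, local_background, saturated, low_signal, off_grid``.
    """
    if refine:
        layout = locate_spots(image, layout, search_window=search_window)
    rows = []
    for _, spot in layout.spots.iterrows():
        radius = float(spot["radius"])
        m = integrate_spot(
            image,
            (float(spot["row"]), float(spot["col"])),
            radius,
            annulus=(radius + annulus_offsets[0], radius + annulus_offsets[1]),
        )
        m.spot_id = spot["spot_id"]
        if bool(spot.get("low_signal", False)):
            m.flags["low_signal"] = True
        if bool(spot.get("off_grid", False)):
            m.flags["off_grid"] = True
        row = m.to_dict()
        row["role"] = spot["role"]
        row["sample_id"] = spot["sample_id"]
        row["known_content"] = spot["known_content"]
        rows.append(row)
    cols = [
        "spot_id",
        "role",
        "sample_id",
        "known_content",
        "center_row",
        "center_col",
        "integral_intensity",
        "local_background",
        "saturated",
        "low_signal",
        "off_grid",
    ]
    return pd.DataFrame(rows, columns=cols)
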