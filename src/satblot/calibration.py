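"""Logarithmic standard-curve fitting, inverse prediction and replicate
aggregation.

The intensity-content law is fixed as ``I = a + b * ln(q / q_ref)`` with
``b > 0``; standards are fitted by unweighted least squares and unknowns are
recovered by the closed-form inverse ``q = q_ref * exp((I - a) / b)``.
Before fitting or inversion, the background spot's corrected integral is
subtracted from every spot's corrected integral (floored at a small positive
epsilon).  Contents convert to copies per haploid genome via the mass
fraction: ``copies = (content / 1000) * genome_size_bp / unit_length_bp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .densitometry import SpotLayout

__all__ = [
    "CalibrationCurve",
    "SampleQuant",
    "NonMonotoneCalibrationError",
    "fit_calibration",
    "invert",
    "quantify_sample",
    "content_to_copies",
    "calibrate_from_measurements",
    "quantify_from_measurements",
    "quantify_membrane",
    "NET_INTENSITY_FLOOR",
]

#: Floor applied to background-subtracted intensities before inversion.
NET_INTENSITY_FLOOR = 1e-9


class NonMonotoneCalibrationError(ValueError):
    """Raised when the fitted slope is not positive."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted law ``I = a + b * ln(q / q_ref)`` with its validity domain."""

    a: float
    b: float
    q_ref: float
    residual_sd: float
    domain: tuple[float, float]
    n_standards: int

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise NonMonotoneCalibrationError("calibration slope must be positive")
        if not (0 < self.domain[0] <= self.domain[1]):
            raise ValueError("calibration domain must be a nonempty positive interval")
        if self.n_standards < 3:
            raise ValueError("a calibration needs at least 3 standards")

    def forward(self, content: float | np.ndarray) -> float | np.ndarray:
        return self.a + self.b * np.log(np.asarray(content, dtype=float) / self.q_ref)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "q_ref": self.q_ref,
            "residual_sd": self.residual_sd,
            "domain": list(self.domain),
            "n_standards": self.n_standards,
        }


@dataclass
class SampleQuant:
    """Triplicate-aggregated content estimate for one sample."""

    sample_id: object
    content_mean: float
    content_se: float
    relative_sd: float
    n_replicates: int
    flags: dict[str, bool] = field(
        default_factory=lambda: {"extrapolated": False, "saturated_replicate": False, "low_n": False}
    )
    replicate_contents: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "content_mean": self.content_mean,
            "content_se": self.content_se,
            "relative_sd": self.relative_sd,
            "n_replicates": self.n_replicates,
        }
        d.update(self.flags)
        return d


def fit_calibration(
    standards: Sequence[tuple[float, float]], q_ref: float = 1.0
) -> CalibrationCurve:
    """Least-squares fit of the log law on (known_content, corrected_intensity)
    pairs.

    Requires at least three standards with distinct positive contents.
    Raises :class:`NonMonotoneCalibrationError` when the fitted slope is not
    positive (intensity must increase with content).
    """
    if q_ref <= 0:
        raise ValueError("q_ref must be positive")
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (content, intensity) pairs")
    q, intensity = arr[:, 0], arr[:, 1]
    if np.any(q <= 0):
        raise ValueError("standard contents must be positive")
    if np.unique(q).size < 3:
        raise ValueError("need >= 3 standards with distinct contents")
    x = np.log(q / q_ref)
    b, a = np.polyfit(x, intensity, 1)
    if b <= 0:
        raise NonMonotoneCalibrationError(
            f"calibration is non-monotone (fitted slope {b:.4g} <= 0)"
        )
    resid = intensity - (a + b * x)
    dof = len(q) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return CalibrationCurve(
        a=float(a),
        b=float(b),
        q_ref=q_ref,
        residual_sd=residual_sd,
        domain=(float(q.min()), float(q.max())),
        n_standards=int(len(q)),
    )


def invert(curve: CalibrationCurve, intensity: float) -> tuple[float, bool]:
    """Invert the curve at one corrected intensity.

    Returns ``(content, extrapolated)`` where the flag marks contents outside
    the interval spanned by the standards.  Inversion never fails: the log
    law is globally invertible.
    """
    content = curve.q_ref * math.exp((intensity - curve.a) / curve.b)
    lo, hi = curve.domain
    rtol = 1e-9  # guard against round-off at the domain edges
    extrapolated = content < lo * (1 - rtol) or content > hi * (1 + rtol)
    return content, extrapolated


def quantify_sample(
    sample_id: object,
    replicate_intensities: Sequence[float],
    curve: CalibrationCurve,
    excluded: Sequence[bool] | None = None,
    saturated: Sequence[bool] | None = None,
) -> SampleQuant:
    """Aggregate replicate spot intensities into one content estimate.

    ``excluded`` marks replicates dropped from the aggregate (e.g. saturated
    or off-grid spots).  With fewer than two usable replicates the result is
    returned with the ``low_n`` flag instead of failing; with none, raises.
    ``content_se`` is SD/sqrt(n) and ``relative_sd`` the per-spot CV, SD/mean.
    """
    intensities = np.asarray(replicate_intensities, dtype=float)
    n_total = len(intensities)
    if n_total == 0:
        raise ValueError("no replicate intensities given")
    excluded = np.asarray(excluded if excluded is not None else [False] * n_total, dtype=bool)
    saturated = np.asarray(saturated if saturated is not None else [False] * n_total, dtype=bool)
    usable = ~excluded
    if not usable.any():
        raise ValueError(f"all replicates of sample {sample_id!r} are flagged")

    contents, extrapolated = [], False
    for intensity in intensities[usable]:
        c, ex = invert(curve, float(intensity))
        contents.append(c)
        extrapolated = extrapolated or ex
    contents = np.asarray(contents)
    n = len(contents)
    mean = float(contents.mean())
    sd = float(contents.std(ddof=1)) if n > 1 else 0.0
    return SampleQuant(
        sample_id=sample_id,
        content_mean=mean,
        content_se=sd / math.sqrt(n),
        relative_sd=sd / mean if mean != 0 else 0.0,
        n_replicates=n,
        flags={
            "extrapolated": extrapolated,
            "saturated_replicate": bool(saturated.any()),
            "low_n": n < 2,
        },
        replicate_contents=[float(c) for c in contents],
    )


def content_to_copies(
    content_pg_per_ng: float, unit_length_bp: float, genome_size_bp: float
) -> float:
    """Convert a mass fraction (pg repeat per ng DNA) to copies per haploid
    genome.  1000 pg/ng (pure repeat) with unit length equal to the genome
    size maps to exactly one copy."""
    if content_pg_per_ng < 0:
        raise ValueError("content must be nonnegative")
    if unit_length_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("unit and genome lengths must be positive")
    return (content_pg_per_ng / 1000.0) * genome_size_bp / unit_length_bp


# ---------------------------------------------------------------------------
# Measurement-table plumbing


def _background_value(measurements: pd.DataFrame) -> float:
    bg = measurements[measurements["role"] == "background"]
    if bg.empty:
        return 0.0
    return float(bg["integral_intensity"].mean())


def calibrate_from_measurements(
    measurements: pd.DataFrame, q_ref: float = 1.0
) -> tuple[CalibrationCurve, float]:
    """Fit a curve from a MeasurementTable.

    Subtracts the mean background-spot corrected integral from every standard
    (floored at a small positive epsilon) and fits on unsaturated calibration
    spots.  Returns ``(curve, background_value)`` so samples can be corrected
    identically.
    """
    background = _background_value(measurements)
    cal = measurements[measurements["role"] == "calibration"]
    if "saturated" in cal.columns:
        cal = cal[~cal["saturated"].astype(bool)]
    if len(cal) < 3:
        raise ValueError("fewer than 3 usable calibration spots")
    net = np.maximum(cal["integral_intensity"].to_numpy(float) - background, NET_INTENSITY_FLOOR)
    standards = list(zip(cal["known_content"].to_numpy(float), net))
    return fit_calibration(standards, q_ref=q_ref), background


def quantify_from_measurements(
    measurements: pd.DataFrame,
    curve: CalibrationCurve,
    background_value: float,
) -> pd.DataFrame:
    """Aggregate sample-replicate measurements into a SampleQuant table."""
    samples = measurements[measurements["role"] == "sample_replicate"]
    rows = []
    for sid, group in samples.groupby("sample_id", sort=False):
        net = np.maximum(
            group["integral_intensity"].to_numpy(float) - background_value, NET_INTENSITY_FLOOR
        )
        saturated = (
            group["saturated"].to_numpy(bool)
            if "saturated" in group.columns
            else np.zeros(len(group), dtype=bool)
        )
        quant = quantify_sample(sid, net, curve, excluded=saturated, saturated=saturated)
        rows.append(quant.to_dict())
    return pd.DataFrame(rows)


def quantify_membrane(image, layout: SpotLayout, q_ref: float = 1.0, refine: bool = False):
    """Convenience pipeline: densitometry -> calibration -> sample table.

    Returns ``(curve, sample_table, measurements)``.
    """
    from .densitometry import measure_membrane

    measurements = measure_membrane(image, layout, refine=refine)
    curve, background = calibrate_from_measurements(measurements, q_ref=q_ref)
    table = quantify_from_measurements(measurements, curve, background)
    return curve, table, measurements
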