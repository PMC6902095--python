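"""Synthetic membranes, cohorts, paired-therapy tables and brain panels.

Every generator is a pure function of its spec and seed, so downstream
densitometry, calibration and statistics can be exercised end to end with a
known ground truth and no external data.

Signal model: a spot loaded with content ``q`` (pg repeat per ng DNA) renders
with integral intensity ``clamp(a + b*ln(q/q_ref), 0, saturation) +
background_level``; the background spot (DNA non-homologous to the probe)
carries ``background_level`` alone.  Measurement noise is multiplicative and
lognormal on the content scale: an extraction stage shared by a sample's
replicates and an assay stage independent per spot, with
``sigma = ln(1 + cv)`` so the stated relative errors are exact parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .densitometry import MembraneImage, SpotLayout

__all__ = [
    "SignalModel",
    "NoiseModel",
    "CohortSpec",
    "TherapySpec",
    "BrainPanelSpec",
    "OverlapError",
    "make_layout",
    "make_membrane",
    "make_cohort",
    "make_paired_therapy",
    "make_brain_panel",
    "default_standard_contents",
    "CONTENT_FLOOR",
]

#: Lower clip for generated cohort contents, pg/ng.
CONTENT_FLOOR = 1.0


class OverlapError(ValueError):
    """Raised when two spot footprints overlap on the raster."""


@dataclass(frozen=True)
class SignalModel:
    """Logarithmic intensity-content law with saturation and background.

    ``integral(q) = clamp(intercept_a + slope_b * ln(q / q_ref), 0,
    saturation_level) + background_level``.
    """

    intercept_a: float = 20_000.0
    slope_b: float = 4_000.0
    q_ref: float = 1.0
    saturation_level: float = 55_000.0
    background_level: float = 1_500.0

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive")
        if self.q_ref <= 0:
            raise ValueError("q_ref must be positive")
        if not (self.saturation_level > self.background_level >= 0):
            raise ValueError("require saturation_level > background_level >= 0")

    def forward(self, content: float | np.ndarray) -> float | np.ndarray:
        """Noise-free integral intensity for a given content (pg/ng)."""
        q = np.asarray(content, dtype=np.float64)
        specific = np.clip(
            self.intercept_a + self.slope_b * np.log(q / self.q_ref),
            0.0,
            self.saturation_level,
        )
        out = specific + self.background_level
        return float(out) if np.isscalar(content) else out


@dataclass(frozen=True)
class NoiseModel:
    """Noise stages of the simulated assay.

    ``assay_cv`` is the relative SD of per-spot multiplicative content noise
    (the hybridization-and-densitometry stage, nominally 5%); ``extraction_cv``
    is the per-sample stage applied before spotting (DNA isolation dominates
    the total error).  ``pixel_sd`` adds Gaussian read noise per pixel and
    ``gradient_amplitude`` a smooth background ramp across the membrane.
    """

    assay_cv: float = 0.05
    extraction_cv: float = 0.0
    pixel_sd: float = 0.0
    gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("assay_cv", "extraction_cv", "pixel_sd", "gradient_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Moments and covariate model of one synthetic subject group."""

    group_label: str
    n: int
    mean_content: float
    sd_content: float
    distribution_family: str = "normal"
    birth_year_range: tuple[int, int] = (1935, 2001)
    panss_beta0: float | None = None
    panss_beta1: float | None = None
    panss_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_content < 0:
            raise ValueError("sd_content must be nonnegative")
        if self.distribution_family not in ("normal", "lognormal"):
            raise ValueError("distribution_family must be 'normal' or 'lognormal'")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (lo, hi) with lo <= hi")


@dataclass(frozen=True)
class TherapySpec:
    """Shrinkage-toward-setpoint model for paired pre/post contents.

    ``post = setpoint_mu + kappa * (pre - setpoint_mu) + eps``; with
    ``eps_sd -> 0`` and ``setpoint_mu = pre_mean`` the follow-up CV is
    ``kappa`` times the baseline CV.
    """

    n: int
    pre_mean: float
    pre_sd: float
    setpoint_mu: float
    kappa: float
    eps_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.pre_sd < 0 or self.eps_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class BrainPanelSpec:
    """Two-component satellite mixture with constant rDNA and a telomere
    repeat decreasing linearly in the satellite content."""

    n_regions: int = 8
    low_mean: float = 7.3
    low_sd: float = 2.5
    n_low: int = 3
    high_mean: float = 26.8
    high_sd: float = 4.8
    rdna_copies_mean: float = 381.0
    rdna_copies_sd: float = 7.0
    tr_intercept: float = 30.0
    tr_slope: float = -0.6
    tr_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not (0 < self.n_low < self.n_regions):
            raise ValueError("require 0 < n_low < n_regions")
        if self.high_mean <= self.low_mean:
            raise ValueError("degenerate mixture: require high_mean > low_mean")


def default_standard_contents(n: int = 6, lo: float = 6.0, hi: float = 40.0) -> np.ndarray:
    """Calibration-standard contents, log-uniformly spaced over [lo, hi] pg/ng."""
    return np.exp(np.linspace(math.log(lo), math.log(hi), n))


def make_layout(
    sample_ids: Sequence[object],
    n_replicates: int = 3,
    standard_contents: Sequence[float] | None = None,
    n_background: int = 1,
    radius: float = 9.0,
    pitch: float = 40.0,
    grid_rows: int = 7,
    margin: float | None = None,
) -> SpotLayout:
    """Column-major grid layout: standards and the background spot first
    (one marked column), then each sample's replicates contiguously.

    Returns a layout whose nominal centers sit on a ``pitch``-spaced grid
    with ``grid_rows`` spots per column, starting at ``margin`` from the
    top-left corner.
    """
    if standard_contents is None:
        standard_contents = default_standard_contents()
    standard_contents = np.asarray(standard_contents, dtype=float)
    if np.any(standard_contents <= 0):
        raise ValueError("standard contents must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if margin is None:
        margin = pitch

    records: list[dict] = []
    for i, q in enumerate(standard_contents):
        records.append(
            dict(role="calibration", sample_id=f"std_{i + 1}", known_content=float(q))
        )
    for i in range(n_background):
        records.append(dict(role="background", sample_id=f"bg_{i + 1}", known_content=np.nan))
    for sid in sample_ids:
        for _ in range(n_replicates):
            records.append(dict(role="sample_replicate", sample_id=sid, known_content=np.nan))

    rows = []
    for k, rec in enumerate(records):
        gi, gj = k % grid_rows, k // grid_rows
        rows.append(
            dict(
                spot_id=f"spot_{k:04d}",
                role=rec["role"],
                sample_id=rec["sample_id"],
                row=margin + gi * pitch,
                col=margin + gj * pitch,
                radius=radius,
                known_content=rec["known_content"],
            )
        )
    return SpotLayout(pd.DataFrame(rows))


def _layout_image_shape(layout: SpotLayout, pad: float) -> tuple[int, int]:
    df = layout.spots
    h = int(math.ceil(df["row"].max() + df["radius"].max() + pad)) + 1
    w = int(math.ceil(df["col"].max() + df["radius"].max() + pad)) + 1
    return h, w


def _check_no_overlap(layout: SpotLayout) -> None:
    df = layout.spots
    r = df["row"].to_numpy(float)
    c = df["col"].to_numpy(float)
    rad = df["radius"].to_numpy(float)
    for i in range(len(df)):
        d = np.hypot(r - r[i], c - c[i])
        clash = (d < rad + rad[i]) & (np.arange(len(df)) > i)
        if clash.any():
            j = int(np.nonzero(clash)[0][0])
            raise OverlapError(
                f"spot footprints overlap: {df['spot_id'].iloc[i]!r} and {df['spot_id'].iloc[j]!r}"
            )


def _render_spot(
    pixels: np.ndarray, row: float, col: float, radius: float, target_integral: float
) -> None:
    """Add an isotropic Gaussian spot (sigma = radius/3, truncated at the
    circular footprint) whose pixel sum equals ``target_integral`` exactly."""
    if target_integral <= 0:
        return
    sigma = radius / 3.0
    r_lo = max(int(math.floor(row - radius)), 0)
    r_hi = min(int(math.ceil(row + radius)), pixels.shape[0] - 1)
    c_lo = max(int(math.floor(col - radius)), 0)
    c_hi = min(int(math.ceil(col + radius)), pixels.shape[1] - 1)
    rr = np.arange(r_lo, r_hi + 1, dtype=np.float64)[:, None]
    cc = np.arange(c_lo, c_hi + 1, dtype=np.float64)[None, :]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    profile = np.exp(-d2 / (2.0 * sigma**2))
    profile[d2 > radius**2] = 0.0
    total = profile.sum()
    if total <= 0:
        raise ValueError("spot footprint contains no pixels")
    pixels[r_lo : r_hi + 1, c_lo : c_hi + 1] += profile * (target_integral / total)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.log1p(cv)
    return np.exp(rng.normal(0.0, sigma, size=size))


def make_membrane(
    layout: SpotLayout,
    true_contents: dict[object, float],
    signal: SignalModel | None = None,
    noise: NoiseModel | None = None,
    image_shape: tuple[int, int] | None = None,
) -> tuple[MembraneImage, pd.DataFrame]:
    """Render a membrane image and its per-spot truth table.

    Parameters
    ----------
    layout:
        must contain >= 3 calibration spots with distinct positive contents,
        >= 1 background spot, and a fixed replicate count per sample.
    true_contents:
        mapping sample_id -> true content in pg/ng for every sample in the
        layout.
    image_shape:
        (rows, cols); computed from the layout when omitted.  Raising when
        any spot footprint (plus background annulus room) does not fit.

    Returns
    -------
    (MembraneImage, TruthTable)
        The image is an exact float raster (quantize/save separately).  The
        truth table records, per spot, the true and noise-perturbed contents
        and the forward-model integral actually rendered.
    """
    signal = signal or SignalModel()
    noise = noise or NoiseModel()

    cal = layout.calibration
    if len(cal) < 3 or np.unique(cal["known_content"].to_numpy(float)).size < 3:
        raise ValueError("layout needs >= 3 calibration spots with distinct contents")
    if len(layout.background) < 1:
        raise ValueError("layout needs at least one background spot")
    sample_ids = list(dict.fromkeys(layout.sample_replicates["sample_id"]))
    missing = [s for s in sample_ids if s not in true_contents]
    if missing:
        raise ValueError(f"true_contents missing sample ids: {missing}")
    for sid, q in true_contents.items():
        if q <= 0:
            raise ValueError(f"true content of sample {sid!r} must be positive")

    _check_no_overlap(layout)
    pad = max(DEFAULT_ANNULUS_PAD, 0.0)
    min_shape = _layout_image_shape(layout, pad)
    if image_shape is None:
        image_shape = min_shape
    elif image_shape[0] < min_shape[0] or image_shape[1] < min_shape[1]:
        raise ValueError(f"image too small: need at least {min_shape}, got {image_shape}")
    lo_r = layout.spots["row"].min() - layout.spots["radius"].max() - pad
    lo_c = layout.spots["col"].min() - layout.spots["radius"].max() - pad
    if lo_r < 0 or lo_c < 0:
        raise ValueError("image too small: spots too close to the top-left border")

    rng = np.random.default_rng(noise.seed)
    extraction = dict(
        zip(sample_ids, _lognormal_factor(rng, noise.extraction_cv, len(sample_ids)))
    )

    pixels = np.zeros(image_shape, dtype=np.float64)
    if noise.gradient_amplitude > 0:
        rr = np.linspace(0.0, 1.0, image_shape[0])[:, None]
        cc = np.linspace(0.0, 1.0, image_shape[1])[None, :]
        pixels += noise.gradient_amplitude * (rr + cc) / 2.0

    df = layout.spots
    assay = _lognormal_factor(rng, noise.assay_cv, len(df))
    truth_rows = []
    for k, (_, spot) in enumerate(df.iterrows()):
        role = spot["role"]
        if role == "background":
            true_q = np.nan
            perturbed_q = np.nan
            integral = signal.background_level
        else:
            if role == "calibration":
                true_q = float(spot["known_content"])
                perturbed_q = true_q * assay[k]
            else:
                true_q = float(true_contents[spot["sample_id"]])
                perturbed_q = true_q * extraction[spot["sample_id"]] * assay[k]
            integral = signal.forward(perturbed_q)
        _render_spot(pixels, float(spot["row"]), float(spot["col"]), float(spot["radius"]), integral)
        truth_rows.append(
            dict(
                spot_id=spot["spot_id"],
                role=role,
                sample_id=spot["sample_id"],
                true_content=true_q,
                perturbed_content=perturbed_q,
                forward_integral=integral,
                row=float(spot["row"]),
                col=float(spot["col"]),
            )
        )

    if noise.pixel_sd > 0:
        pixels += rng.normal(0.0, noise.pixel_sd, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)
    return MembraneImage(pixels), pd.DataFrame(truth_rows)


#: Extra border room kept around spots so the default background annulus fits.
DEFAULT_ANNULUS_PAD = 7.0


def _content_draws(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    if spec.sd_content == 0:
        return np.full(spec.n, spec.mean_content, dtype=float)
    if spec.distribution_family == "normal":
        draws = rng.normal(spec.mean_content, spec.sd_content, size=spec.n)
    else:
        # lognormal with matching mean and SD
        var = spec.sd_content**2
        mu2 = spec.mean_content**2
        sigma2 = math.log1p(var / mu2)
        mu = math.log(spec.mean_content) - sigma2 / 2.0
        draws = rng.lognormal(mu, math.sqrt(sigma2), size=spec.n)
    return np.clip(draws, CONTENT_FLOOR, None)


def make_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Generate one cohort table.

    Columns: ``subject_id, group, birth_year, content`` and, when the spec
    carries a PANSS model, ``panss = beta0 + beta1 * content + N(0, sd)``.
    Contents are clipped below at 1 pg/ng.
    """
    rng = np.random.default_rng(seed)
    content = _content_draws(rng, spec)
    lo, hi = spec.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=spec.n)
    df = pd.DataFrame(
        {
            "subject_id": [f"{spec.group_label}_{i + 1:04d}" for i in range(spec.n)],
            "group": spec.group_label,
            "birth_year": birth_year,
            "content": content,
        }
    )
    if spec.panss_beta0 is not None and spec.panss_beta1 is not None:
        eps = rng.normal(0.0, spec.panss_sd, size=spec.n) if spec.panss_sd > 0 else 0.0
        df["panss"] = spec.panss_beta0 + spec.panss_beta1 * content + eps
    return df


def make_paired_therapy(spec: TherapySpec) -> pd.DataFrame:
    """Generate paired baseline/follow-up contents under the shrinkage law."""
    rng = np.random.default_rng(spec.seed)
    pre = np.clip(rng.normal(spec.pre_mean, spec.pre_sd, size=spec.n), CONTENT_FLOOR, None)
    eps = rng.normal(0.0, spec.eps_sd, size=spec.n) if spec.eps_sd > 0 else np.zeros(spec.n)
    post = spec.setpoint_mu + spec.kappa * (pre - spec.setpoint_mu) + eps
    post = np.clip(post, CONTENT_FLOOR, None)
    return pd.DataFrame(
        {
            "subject_id": [f"pt_{i + 1:03d}" for i in range(spec.n)],
            "content_pre": pre,
            "content_post": post,
        }
    )


def make_brain_panel(spec: BrainPanelSpec) -> pd.DataFrame:
    """Generate a per-region repeat panel: bimodal satellite content,
    near-constant rDNA copies, and a telomere repeat anti-correlated with
    the satellite."""
    rng = np.random.default_rng(spec.seed)
    n_high = spec.n_regions - spec.n_low
    low = rng.normal(spec.low_mean, spec.low_sd, size=spec.n_low)
    high = rng.normal(spec.high_mean, spec.high_sd, size=n_high)
    satiii = np.clip(np.concatenate([low, high]), 0.1, None)
    subgroup_true = np.array(["low"] * spec.n_low + ["high"] * n_high)
    perm = rng.permutation(spec.n_regions)
    satiii, subgroup_true = satiii[perm], subgroup_true[perm]
    rdna = rng.normal(spec.rdna_copies_mean, spec.rdna_copies_sd, size=spec.n_regions)
    eps = rng.normal(0.0, spec.tr_sd, size=spec.n_regions) if spec.tr_sd > 0 else 0.0
    tr = spec.tr_intercept + spec.tr_slope * satiii + eps
    return pd.DataFrame(
        {
            "region": [f"region_{i + 1}" for i in range(spec.n_regions)],
            "satIII": satiii,
            "rdna": rdna,
            "tr": tr,
            "subgroup_true": subgroup_true,
        }
    )
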