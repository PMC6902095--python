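"""Run configuration: a strict, nested schema with defaults that mirror the
documented assay constants (50 ng per spot, triplicate samples, six
standards, 20 pg/ng severity threshold, significance at p <= 0.01).

Unknown keys are errors, not warnings.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from ..synthetic_data import (
    BrainPanelSpec,
    CohortSpec,
    NoiseModel,
    SignalModel,
    TherapySpec,
)

__all__ = ["RunConfig", "ConfigError", "default_config_dict"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a run config."""


#: Closed group vocabulary used by cohort records.
GROUPS = ("HC", "SZ_Mminus", "SZ_Mplus", "H_SZ_Mplus", "NH_SZ_Mplus")


def default_config_dict() -> dict:
    """Defaults for the end-to-end demo.

    Cohort moments follow the published group descriptives; the therapy
    block shrinks a CV-0.31 baseline roughly in half; the brain block uses
    the published subgroup means and rDNA copy statistics.
    """
    return {
        "seed": 0,
        "output_dir": "satblot_demo",
        "rounding": {"cv_dp": 2, "content_dp": 1, "ratio_dp": 1},
        "signal": {
            "intercept_a": 20000.0,
            "slope_b": 4000.0,
            "q_ref": 1.0,
            "saturation_level": 55000.0,
            "background_level": 1500.0,
        },
        "noise": {
            "assay_cv": 0.05,
            "extraction_cv": 0.0,
            "pixel_sd": 0.0,
            "gradient_amplitude": 0.0,
        },
        "membrane": {
            "n_samples": 30,
            "n_replicates": 3,
            "n_standards": 6,
            "standard_min": 6.0,
            "standard_max": 40.0,
            "content_min": 6.0,
            "content_max": 40.0,
            "radius": 9.0,
            "pitch": 40.0,
            "grid_rows": 7,
        },
        "cohorts": [
            {"group_label": "HC", "n": 401, "mean_content": 22.0, "sd_content": 6.7},
            {
                "group_label": "SZ_Mminus",
                "n": 283,
                "mean_content": 17.0,
                "sd_content": 5.9,
                "panss_beta0": 118.0,
                "panss_beta1": -1.0,
                "panss_sd": 25.0,
            },
            {
                "group_label": "SZ_Mplus",
                "n": 271,
                "mean_content": 18.4,
                "sd_content": 5.8,
                "panss_beta0": 115.0,
                "panss_beta1": -1.0,
                "panss_sd": 25.0,
            },
            {
                "group_label": "H_SZ_Mplus",
                "n": 143,
                "mean_content": 22.7,
                "sd_content": 5.4,
                "panss_beta0": 105.0,
                "panss_beta1": -1.0,
                "panss_sd": 22.0,
            },
            {
                "group_label": "NH_SZ_Mplus",
                "n": 143,
                "mean_content": 14.7,
                "sd_content": 3.0,
                "panss_beta0": 95.0,
                "panss_beta1": -1.0,
                "panss_sd": 22.0,
            },
        ],
        "comparisons": [
            ["HC", "SZ_Mminus"],
            ["HC", "SZ_Mplus"],
            ["HC", "H_SZ_Mplus"],
            ["HC", "NH_SZ_Mplus"],
            ["H_SZ_Mplus", "NH_SZ_Mplus"],
            ["SZ_Mminus", "SZ_Mplus"],
        ],
        "stratification": {"cut_year": 1990},
        "therapy": {
            "n": 93,
            "pre_mean": 17.0,
            "pre_sd": 5.27,
            "setpoint_mu": 17.0,
            "kappa": 0.45,
            "eps_sd": 0.94,
        },
        "panss": {"threshold": 20.0},
        "brain": {
            "n_regions": 8,
            "low_mean": 7.3,
            "low_sd": 2.5,
            "n_low": 3,
            "high_mean": 26.8,
            "high_sd": 4.8,
            "rdna_copies_mean": 381.0,
            "rdna_copies_sd": 7.0,
            "tr_intercept": 30.0,
            "tr_slope": -0.6,
            "tr_sd": 1.5,
        },
    }


def _check_keys(given: Mapping, allowed: Mapping, path: str) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or '<root>'}: {sorted(unknown)}")


def _merge(defaults: Any, override: Any, path: str = "") -> Any:
    """Recursively overlay ``override`` on ``defaults`` with strict keys."""
    if override is None:
        return copy.deepcopy(defaults)
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"expected a mapping at {path or '<root>'}")
        _check_keys(override, defaults, path)
        out = {}
        for key, value in defaults.items():
            sub = f"{path}.{key}" if path else key
            if key in ("cohorts", "comparisons"):  # list blocks replace wholesale
                out[key] = copy.deepcopy(override.get(key, value))
            else:
                out[key] = _merge(value, override.get(key), sub)
        return out
    return copy.deepcopy(override)


@dataclass
class RunConfig:
    """Validated run configuration."""

    data: dict = field(default_factory=default_config_dict)

    def __post_init__(self) -> None:
        merged = _merge(default_config_dict(), self.data if self.data else None)
        self.data = merged
        # eager validation: construct every spec block once
        _ = (self.signal, self.noise, self.cohort_specs, self.therapy_spec, self.brain_spec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls(raw)

    # -- typed views -------------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def signal(self) -> SignalModel:
        return SignalModel(**self.data.get("signal", {}))

    def noise_model(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(**self.data.get("noise", {}), seed=self.seed if seed is None else seed)

    @property
    def noise(self) -> NoiseModel:
        return self.noise_model()

    @property
    def cohort_specs(self) -> list[CohortSpec]:
        specs = []
        for block in self.data.get("cohorts", []):
            spec = CohortSpec(**block)
            if spec.group_label not in GROUPS:
                raise ConfigError(
                    f"group_label {spec.group_label!r} not in closed vocabulary {GROUPS}"
                )
            specs.append(spec)
        return specs

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        return [tuple(pair) for pair in self.data.get("comparisons", [])]

    def therapy_spec_with_seed(self, seed: int) -> TherapySpec:
        return TherapySpec(**self.data.get("therapy", {}), seed=seed)

    @property
    def therapy_spec(self) -> TherapySpec:
        return self.therapy_spec_with_seed(self.seed)

    def brain_spec_with_seed(self, seed: int) -> BrainPanelSpec:
        return BrainPanelSpec(**self.data.get("brain", {}), seed=seed)

    @property
    def brain_spec(self) -> BrainPanelSpec:
        return self.brain_spec_with_seed(self.seed)

    @property
    def membrane(self) -> dict:
        return dict(self.data["membrane"])

    @property
    def rounding(self) -> dict:
        return dict(self.data["rounding"])

    def config_hash(self) -> str:
        """Stable hash of the fully-merged configuration."""
        canonical = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()
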