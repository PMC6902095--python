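"""End-to-end demo: simulation -> densitometry -> calibration -> statistics.

Writes a deterministic artifact directory (images, tables, JSON reports,
figures) plus a manifest listing every file with its SHA-256 checksum, the
seed and the config hash.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .. import __version__
from ..brain_panel import analyze_panel
from ..calibration import quantify_membrane
from ..cohort_stats import (
    compare_groups,
    ecdf,
    paired_therapy_analysis,
    panss_association,
    stratify_by_birth_year,
)
from ..synthetic_data import (
    default_standard_contents,
    make_brain_panel,
    make_cohort,
    make_layout,
    make_membrane,
    make_paired_therapy,
)
from .config import RunConfig

__all__ = ["run_full_demo"]

# fixed seed offsets for the independent generator stages
_COHORT_SEED_BASE = 100
_THERAPY_SEED = 200
_BRAIN_SEED = 300


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_demo(config: RunConfig, output_dir: str | Path | None = None) -> Path:
    """Run the whole pipeline on synthetic data; returns the artifact dir."""
    outdir = Path(output_dir or config.data["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng = np.random.default_rng(seed)

    # --- membrane stage ---------------------------------------------------
    mem = config.membrane
    sample_ids = [f"sample_{i + 1:03d}" for i in range(mem["n_samples"])]
    contents = np.exp(
        rng.uniform(math.log(mem["content_min"]), math.log(mem["content_max"]), len(sample_ids))
    )
    true_contents = dict(zip(sample_ids, contents))
    layout = make_layout(
        sample_ids,
        n_replicates=mem["n_replicates"],
        standard_contents=default_standard_contents(
            mem["n_standards"], mem["standard_min"], mem["standard_max"]
        ),
        radius=mem["radius"],
        pitch=mem["pitch"],
        grid_rows=mem["grid_rows"],
    )
    image, truth = make_membrane(layout, true_contents, config.signal, config.noise_model(seed))
    image.save(outdir / "membrane.tif")
    image.save(outdir / "membrane.png")
    layout.to_csv(outdir / "layout.csv")
    truth.to_csv(outdir / "truth.csv", index=False)

    curve, sample_table, measurements = quantify_membrane(image, layout)
    measurements.to_csv(outdir / "measurements.csv", index=False)
    sample_table.to_csv(outdir / "sample_quant.csv", index=False)
    _write_json(outdir / "calibration.json", curve.to_dict())

    # --- cohort stage -----------------------------------------------------
    cohorts = []
    for i, spec in enumerate(config.cohort_specs):
        cohorts.append(make_cohort(spec, seed=seed + _COHORT_SEED_BASE + i))
    cohort = pd.concat(cohorts, ignore_index=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)

    report = compare_groups(cohort, config.comparisons)
    _write_json(outdir / "comparisons.json", report.to_dict())

    cut = int(config.data["stratification"]["cut_year"])
    older, younger = stratify_by_birth_year(cohort, cut_year=cut)
    ecdf_frames = []
    for stratum_name, stratum in (("older", older), ("younger", younger), ("all", cohort)):
        for label, sub in stratum.groupby("group"):
            e = ecdf(sub["content"])
            e.insert(0, "stratum", stratum_name)
            e.insert(1, "group", label)
            ecdf_frames.append(e)
    pd.concat(ecdf_frames, ignore_index=True).to_csv(outdir / "ecdf.csv", index=False)

    # --- therapy stage ----------------------------------------------------
    paired = make_paired_therapy(config.therapy_spec_with_seed(seed + _THERAPY_SEED))
    paired.to_csv(outdir / "therapy_pairs.csv", index=False)
    therapy = paired_therapy_analysis(paired["content_pre"], paired["content_post"])
    _write_json(outdir / "therapy.json", therapy.to_dict())

    # --- severity-score stage --------------------------------------------
    sz = cohort[cohort["panss"].notna()] if "panss" in cohort.columns else cohort.iloc[0:0]
    panss_payload: dict = {"n": int(len(sz))}
    if len(sz) >= 3:
        panss = panss_association(
            sz["content"], sz["panss"], threshold=float(config.data["panss"]["threshold"])
        )
        panss_payload.update(panss.to_dict())
    _write_json(outdir / "panss.json", panss_payload)

    # --- brain-panel stage ------------------------------------------------
    panel = make_brain_panel(config.brain_spec_with_seed(seed + _BRAIN_SEED))
    panel.to_csv(outdir / "brain_panel.csv", index=False)
    _write_json(outdir / "brain_panel.json", analyze_panel(panel))

    # --- figures ----------------------------------------------------------
    _figures(outdir, sample_table, cohort, paired, panel)

    # --- manifest ---------------------------------------------------------
    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json" and p.is_file())
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "files": {p.name: _sha256(p) for p in files},
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def _figures(outdir: Path, sample_table, cohort, paired, panel) -> None:
    # ranked recovered contents (membrane demo)
    fig, ax = plt.subplots(figsize=(6, 4))
    ranked = np.sort(sample_table["content_mean"].to_numpy(float))
    ax.errorbar(
        np.arange(1, len(ranked) + 1),
        ranked,
        yerr=np.sort(sample_table["content_se"].to_numpy(float)),
        fmt="o",
        ms=3,
        lw=0.8,
    )
    ax.set_xlabel("sample rank")
    ax.set_ylabel("content, pg/ng DNA")
    ax.set_title("Ranked recovered contents")
    fig.savefig(outdir / "fig_ranked_contents.png", dpi=120)
    plt.close(fig)

    # cumulative distributions per group
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in cohort.groupby("group"):
        e = ecdf(sub["content"])
        ax.step(e["value"], e["cumulative_fraction"], where="post", label=label)
    ax.set_xlabel("content, pg/ng DNA")
    ax.set_ylabel("cumulative fraction")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "fig_ecdf.png", dpi=120)
    plt.close(fig)

    # paired pre/post ranked by baseline
    fig, ax = plt.subplots(figsize=(6, 4))
    order = np.argsort(paired["content_pre"].to_numpy(float))
    ax.plot(paired["content_pre"].to_numpy(float)[order], "o", ms=3, label="baseline")
    ax.plot(paired["content_post"].to_numpy(float)[order], "s", ms=3, label="follow-up")
    ax.set_xlabel("patient (ranked by baseline)")
    ax.set_ylabel("content, pg/ng DNA")
    ax.legend()
    fig.savefig(outdir / "fig_therapy.png", dpi=120)
    plt.close(fig)

    # telomere repeat vs satellite content
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(panel["satIII"], panel["tr"], "o")
    ax.set_xlabel("satellite content, pg/ng DNA")
    ax.set_ylabel("telomere repeat content")
    fig.savefig(outdir / "fig_tr_vs_satiii.png", dpi=120)
    plt.close(fig)
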