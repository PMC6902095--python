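# satblot

Quantification of tandem-repeat content from dot-blot membranes, plus the
downstream cohort statistics — exercised end to end on synthetic data.

The package covers four stages:

1. **Synthetic data** (`satblot.synthetic_data`) — renders membrane images
   (triplicate 50-ng sample spots, six calibration standards with known
   content, one non-homologous background spot) under a logarithmic
   intensity–content law with multiplicative lognormal noise stages
   (per-spot assay noise, per-sample extraction noise), and generates
   cohort tables, paired pre/post therapy tables (shrinkage toward a
   setpoint) and multi-repeat brain panels. Every generator is a pure
   function of its spec and seed.
2. **Densitometry** (`satblot.densitometry`) — spot-center refinement by
   intensity-weighted centroiding, and background-corrected integral spot
   intensities (sum over the disk minus area × median of a surrounding
   annulus), with saturation / low-signal / off-grid flags.
3. **Calibration** (`satblot.calibration`) — least-squares fit of
   `I = a + b·ln(q/q_ref)` on the standards, closed-form inversion with
   extrapolation flagging, triplicate aggregation into content ± SE with
   per-spot CV, and conversion of mass fractions (pg/ng) to copies per
   haploid genome.
4. **Statistics** (`satblot.cohort_stats`, `satblot.brain_panel`) — group
   descriptives, Mann–Whitney U (exact enumeration for small untied
   samples, tie/continuity-corrected normal approximation otherwise),
   two-sample Kolmogorov–Smirnov with a signed D and the asymptotic
   Kolmogorov tail probability ("α"), birth-year stratification, ECDF
   export, paired-therapy analysis, severity-score association, 1-D
   two-means bimodal partitioning, rDNA constancy checks and repeat
   correlations. Significance is fixed at p ≤ 0.01, two-sided.

## Command line

All functionality is reachable through the `satblot` entry point:

```bash
satblot simulate-membrane --seed 1 -o mem/        # TIFF/PNG + layout + truth CSVs
satblot quantify-image --image mem/membrane.tif --layout mem/layout.csv --out meas.csv
satblot calibrate --measurements meas.csv --out calibration.json
satblot quantify  --measurements meas.csv --out samples.csv
satblot simulate-cohort --seed 1 --out cohort.csv
satblot compare --cohort cohort.csv --pairs "HC:NH_SZ_Mplus" --out cmp.json
satblot therapy --pairs-csv pairs.csv --out therapy.json
satblot panss --cohort cohort.csv --out panss.json
satblot brain-panel --panel panel.csv --out brain.json
satblot demo --seed 1 -o demo/                    # full chained pipeline + figures
```

Configuration is a strict YAML schema (unknown keys are errors); see
`satblot.cli_io.default_config_dict()` for every key and its default. The
`demo` subcommand chains simulation → densitometry → calibration →
statistics and writes a manifest with SHA-256 checksums; identical config
and seed reproduce identical manifests.

## Layout and file formats

Images are written as 16-bit grayscale TIFF or PNG. Spot layouts are CSVs
with columns `spot_id, role, sample_id, row, col, radius, known_content`
(roles: `sample_replicate`, `calibration`, `background`; positions in
pixels, origin top-left, row-major). Measurement tables, sample tables,
cohorts, ECDFs and panels are plain CSV; reports are JSON.
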