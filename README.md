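# redoxhcs

Analysis pipeline for ratiometric **mt-roGFP** high-content screening of
mitochondrial damage, with a fully ground-truthed synthetic-plate generator.

Mitochondrially targeted redox-sensitive GFP (mt-roGFP) shifts its
excitation spectrum with the thiol redox state of the matrix: oxidation
raises the 405-nm-excited emission and lowers the 488-nm-excited emission,
so the per-cell **405/488 emission ratio** reports mitochondrial oxidation —
an early and universal correlate of mitochondrial permeabilization and drug
toxicity. Cells co-expressing nuclear H2B-mCherry can be segmented reliably
even in confluent epithelial monolayers, where threshold segmentation of the
roGFP signal alone merges touching cells.

The package implements, end to end:

- **`redoxhcs.synthetic`** — synthetic plates, time-lapses and flow-style
  event tables with exact per-cell ground truth. The probe is a linear blend
  of reduced/oxidized emission coefficients, calibrated so resting cells
  read ratio 0.5 and a fully oxidized cell reads ≈ 4.4× that; the camera
  model is Poisson shot noise + Gaussian read noise.
- **`redoxhcs.segment`** — both segmentation strategies: Otsu-threshold
  intensity segmentation of the roGFP channel, and nuclear-marker-seeded
  segmentation (watershed splitting) with **perinuclear ring ROIs** built by
  exact Euclidean dilation of each nucleus.
- **`redoxhcs.quantify`** — per-pixel ratio images with validity masking,
  per-cell feature tables (area, per-channel means, granularity, ratio),
  per-well summaries and Pearson correlation.
- **`redoxhcs.screen`** — plate statistics: the screening-window factor
  Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| over per-well ratio means, fold-change
  hit calling against mock-treated controls (default threshold 3×), and a
  head-to-head Z′ comparison of the two segmentation modes.
- **`redoxhcs.kinetics`** — nucleus tracking, single-cell trajectory
  extraction, biphasic change-point detection (exhaustive piecewise-constant
  least squares, order chosen by BIC) and TMRM-loss vs ratio-rise event
  ordering.
- **`redoxhcs.flow`** — flow-cytometry-style per-event ratios and quadrant
  gating against an apoptosis marker.
- **`redoxhcs.cli`** — a `redoxhcs` command with `simulate / segment /
  quantify / screen / kinetics / flow / run` subcommands.

## Worked example

```sh
redoxhcs simulate --out-dir plate --n-negative 4 --n-positive 4 \
    --cells-per-field 30 --seed 1
cat > run.yaml <<'YAML'
plate_dir: plate
layout: plate/layout.csv
out_dir: results
seed: 1
YAML
redoxhcs run --config run.yaml
```

which logs (stderr):

```
[read_plate] {"n_fields": 8}
[quantify] {"n_cells": 223}
[screen] {"z_prime": 0.8135210748136996, "n_hits": 4}
```

and writes `results/cells.csv` (one row per segmented cell: area, channel
means, granularity, 405/488 ratio), `results/wells.csv` (per-well ratio
mean/sd/median and the fraction of cells above the control-derived high-ratio
gate), `results/screen.json` (Z′, arm statistics and fold-change hit calls)
and `results/manifest.json` (config hash + seed; reruns with the same config
and seed are byte-identical). Here the four mock wells average ratios of
0.50–0.54, the four maximum-response wells 1.73–1.87 (≈ 3.5-fold over the
pooled control mean, so all four are hits at the 3× threshold), and
Z′ = 0.81 indicates an excellent screening window.

In Python the same pipeline is three calls:

```python
import redoxhcs as rx

layout = rx.make_layout(n_negative=4, n_positive=4)
fields = rx.simulate_plate(layout, rx.sparse_scene(), seed=1)
records = [r for f, _ in fields for r in rx.analyze_field(f, mode="nuclear-ring")]
wells = rx.well_summary(records, layout)
print(rx.call_hits(wells, layout).z_prime)
```

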