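# anchortrack

Single-cell analysis of transient transfection in a droplet-microfluidic
anchor array: synthetic time-lapse generation, cell segmentation and
tracking, background-subtracted GFP kinetics, and skewness-based detection
of high-producer subpopulations.

## The problem

Transient gene expression in suspension CHO cells is fast but
heterogeneous: after lipoplex transfection, individual cells produce
recombinant protein at wildly different rates, and a small subpopulation
of *high producers* (HPs) can dominate the yield.  Anchor-array
microfluidics makes this heterogeneity measurable: ~1500 capillary anchors
each trap one ~2 nL droplet, cells load randomly (Poisson, λ ≈ 0.45, so
~29% of droplets hold exactly one cell), and agarose immobilization lets
every cell be imaged every 2 h for 62 h.

This package implements the full quantitative chain for such experiments,
and — since the original image data are not public — a forward model that
generates realistic multi-channel stacks with known ground truth, so every
step is testable end to end:

* **formulation** — lipoplex arithmetic: hydrodynamic-focusing dilution,
  molar charge ratio R₊/₋ = (cationic lipid charge)/(pDNA phosphate
  charge), lipoplexes per droplet;
* **chip_model** — anchor-grid geometry, Poisson loading, occupancy MLE,
  single-cell droplet selection;
* **synthetic_timelapse** — per-condition presets (R₊/₋ 5, 3, 1.5),
  ground-truth cell populations, rendered 4-channel TIFF stacks;
* **segmentation** — Otsu thresholding of the cell-tracker channel,
  10–25 µm equivalent-diameter gate, anchor assignment, nearest-centroid
  tracking, viability scoring;
* **kinetics** — per-cell traces I = I_cell − I_back,
  ΔI(t) = I(t) − I₀, OLS production rates, population mean ± M.D.;
* **subpopulations** — skewness series g₁(t), the asymmetry threshold
  T = mode + 3σ̂ (σ̂ from the mirrored sub-mode half of the final ΔI
  distribution), HP/LP classification, HP-specific productivity,
  Kruskal–Wallis / Wilcoxon rank-sum comparisons;
* **pipeline** + CLI — reproducible simulate → segment → trace → classify
  runs keyed by a config hash and one seed.

## Worked example

A simulated R₊/₋ 5 experiment on a 256-anchor chip:

```python
from anchortrack.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(preset="R5", seed=3, rows=16, cols=16),
                      out_dir="runs/demo")
```

prints (via `report.to_json` / `runs/demo/report.json`):

```
n_anchors              256
lambda_hat             0.441    # fitted Poisson loading (true 0.45)
single_cell_fraction   0.328    # droplets with exactly one detected cell
n_cells_analyzed       82       # tracked single-cell traces
viability              0.823    # live fraction from the dead-stain channel
median_r_squared       1.0000   # per-cell ΔI(t) is linear
threshold              644.1    # ΔI threshold from the final distribution
n_hp                   14
hp_percentage          17.07    # preset prevalence 15.27%
hp_specific_productivity 1836.7 # mean final ΔI over HPs only
```

The fitted loading intensity recovers the configured Poisson λ, the
per-cell traces are linear (r² ≫ 0.9) as in the experiment, and the
asymmetry threshold recovers the seeded HP prevalence within binomial
error.  `runs/demo/` also holds the ground truth, detections, traces and
per-cell fits as CSV.

The same run from the shell:

```bash
anchortrack run --preset R5 --seed 3 --rows 16 --cols 16 --out runs/demo
anchortrack ratio --volume-ul 2        # R+/- = 5.357 (nominal 5)
anchortrack simulate --preset R3 --seed 1 --rows 8 --cols 8 --out sim/
anchortrack analyze sim/stack.tiff sim/layout.yaml --out sim/analysis
```

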