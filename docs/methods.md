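# Methods

## Overview

`anchortrack` models and analyses a single-cell transfection experiment in
a droplet-microfluidic anchor array.  Cells are captured one per ~2 nL
droplet in a grid of capillary anchors, immobilized in agarose, transfected
with cationic-liposome/pDNA complexes (lipoplexes), and imaged every 2 h
for 62 h.  The analysis asks how much GFP each cell produces, whether a
minority subpopulation of high producers (HPs) exists, and how HP
abundance, productivity and size depend on the lipoplex charge ratio.

Because no raw image data accompany the study the package is built around
a synthetic-data generator with full ground truth; the analysis pipeline is
written against images, not against the generator's internals, so every
recovery claim is a genuine end-to-end test.

## Formulation arithmetic

Liposomes (EPC/DOTAP/DOPE 50/25/25 mol%, 25 mM total lipid) are assembled
by hydrodynamic focusing, which dilutes the lipid stream by the flow-rate
ratio 11/(11 + 2x55) = 11/121.  The molar charge ratio of a lipoplex is

    R+/- = n(+) / n(-),
    n(+) = [cationic lipid] x V_liposome,
    n(-) = m_pDNA / M_nt,

with only DOTAP (+1 per molecule) counted as cationic and M_nt = 330 g/mol
per nucleotide, the standard convention for N/P-type ratios.  With these
conventions the three experimental preparations (2, 1 and 0.5 uL of
diluted liposomes against 0.07 ug pDNA) give computed ratios 5.36, 2.68
and 1.34, which snap to the nominal labels 5, 3 and 1.5 within a +-20%
window.  The window absorbs the unavoidable ambiguity in how nominal
labels were originally assigned (exact molar masses, rounding); the
computed ratios sit 7-11% from their labels, well inside it, and the next
nominal label is always >2x further away.

Droplet dosing is linear bookkeeping: particle concentration x volume
fraction of lipoplexes in the loading mix x droplet volume.  At the
mid-range concentration 6x10^7 particles/uL this gives ~4.6x10^3 lipoplexes
per 2 nL droplet, order 10^4.

## Chip model

The default layout realizes 1495 anchors as a 65x23 grid.  The anchor
radius (68.7 um) makes a cylinder of the chip's 135 um depth hold 2 nL.
The pitch (200 um, > 2 x radius) is a package choice: the source device's
lateral dimensions are not published, and a compact pitch keeps a
full-chip frame at 1 um/px near 60 Mpx, small enough to render and segment
whole frames in memory.

Cell loading is i.i.d. Poisson per droplet.  The loading intensity is
fitted by maximum likelihood (the sample mean), not by least squares on
the histogram: the MLE is deterministic, efficient, and standard.  At the
experimental intensity lambda = 0.45, P(k=1) = 0.287 — the "about 30%" of
droplets that enter single-cell analysis.

## Synthetic time-lapse generator

The generator emulates the study conditions; its defaults are fixed, not
tuning knobs:

| parameter | default | rationale |
|---|---|---|
| lambda (cells/droplet) | 0.45 | experimental loading density |
| time grid | 0-62 h, step 2 h | experimental imaging schedule |
| HP prevalence | 0.1527 (R5), 0.0872 (R3), 0.0488 (R1.5) | reported HP percentages per condition |
| viability | 0.75 / 0.71 / 0.88 | reported post-transfection viabilities |
| HP diameter multiplier | 1.15 | HP area reported >= 15% larger |
| HP slope multiplier | 4 (R5, R3), 6 (R1.5) | separation is only shown graphically in the source; 4 gives a clearly resolved but overlapping-tail mixture; 6 encodes the ~1.5x higher HP-specific productivity of R1.5 |
| LP diameter | Normal(13, 1.5) um, truncated to (8, 27) | CHO-scale cells; exercises the 10-25 um gate on both sides |
| LP slope | Normal(8, 1.5) counts/h, truncated at 0 | see below |
| baseline I0 | Uniform(10, 30) counts | small nonzero autofluorescence |
| pixel size | 1 um/px | resolves 10-25 um cells with ~100-500 px masks |
| background / read noise | 100 / 5 counts (16-bit) | no camera model is published; chosen so per-trace r^2 lands above 0.9, as observed experimentally |
| disk blur | Gaussian, sigma = 1 px | optical softening of cell edges |

LP production rates are drawn from a truncated normal rather than a
right-skewed law.  This is deliberate: the skewness statistic g1 of the
final Delta I distribution is the detection signal for HPs, and its null
(no-HP) distribution must be centred near zero for the asymmetry threshold
to be meaningful.  A log-normal bulk with any realistic spread would bake
g1 ~ 1 into the null and confound the detector; the near-symmetric bulk
encodes the model assumption that the right tail *is* the subpopulation.

Channel semantics follow the stains: the CellTracker (red) channel renders
viable cells only — the dye is retained by live cells — so kinetic
tracking automatically analyses live cells; the nuclei (blue) channel
renders every cell and serves as the viability denominator; the dead
stain (red_dead) marks non-viable cells.  Dead cells produce no GFP.
Cells are placed without overlap inside their anchor and never move
(agarose immobilization), so the forward model has no motion component.

Rendering is deterministic per (seed, frame, channel): each frame draws
its noise from an independently derived stream, so rendering one frame at
a time is bit-identical to rendering the whole stack.  Two switches exist
for algebraic verification only: `quantize=False` keeps sub-count float64
intensities, and `antialias=False` renders hard binary disks.  With both
off and zero noise, the in-mask mean green intensity equals
I0 + slope x t exactly, which is what lets the test suite demand slope
recovery to 1e-9 relative error.

What the generator does **not** model: photobleaching, cell division and
death dynamics during the time course, focus drift, uneven illumination,
anchor-to-anchor background variation, and cell-shape irregularity.
Passing recovery tests therefore demonstrate the correctness of the
pipeline's logic under the stated noise model, not robustness to every
artefact of real microscopy.

## Segmentation and tracking

Detection per frame: global Otsu threshold on the red channel (the source
only says "thresholded"; the threshold is configurable), connected
components, equivalent diameter = diameter of the circle with the
component's area, gate 10-25 um inclusive at both bounds.  Components are
assigned to the anchor disk containing their centroid; components outside
every anchor are dropped.  Blank or saturated frames yield zero detections
with a warning, never an exception.

Tracking exploits immobility: greedy nearest-centroid matching within each
anchor, 10 um matching radius, ties broken by distance then track id.
Tracks detected in fewer than 90% of frames are discarded; single missing
frames are later filled by linear interpolation.  The gate is applied per
frame; completeness absorbs gate flicker for cells near a bound.

Droplet-level analysis keeps only anchors with exactly one frame-0
detection, mirroring the experiment's single-cell selection.

Viability: a cell is dead when its mask-mean dead-channel signal exceeds
the background mean + 3 SD (background = all pixels outside detection
masks).  The pipeline detects cells for this purpose on the nuclei
channel, so dead cells are counted in the denominator.

## Kinetics

Per frame and cell: I_cell = mean green over the mask, I_back = mean green
over the cell's own anchor disk excluding all (margin-dilated) detection
masks, I = I_cell - I_back, Delta I(t) = I(t) - I(0).  Means (not sums)
make the statistic independent of cell area, so HP calls reflect
production rate rather than size.  Background is local (own anchor) rather
than pooled across empty anchors; this is configurable in principle but
local background also cancels any anchor-level illumination offset.
Adding a constant to every green pixel provably leaves I, Delta I and all
slopes unchanged.

Per-cell production rate: OLS of Delta I on time; r^2 is the squared
Pearson correlation, defined as 0 for constant series.  Population
summaries report the pointwise mean, the mean deviation
M.D. = mean |x - mean| (the dispersion measure used in the source's
figures), and bias-adjusted skewness g1.

## HP detection

The source defines the HP/LP split operationally — a per-experiment
Delta I threshold "based on the asymmetry of the final distribution" —
without giving a formula.  The package's rule uses exactly that asymmetry:

1. mode m of the final Delta I sample, located by the maximum of a
   Gaussian KDE (Silverman bandwidth) on a data-spanning grid;
2. null spread sigma estimated from the left half only, by mirroring
   {x <= m} about m — the sub-mode half is HP-free by construction, so the
   estimate is robust to the right tail;
3. T = m + 3 sigma (multiplier and bandwidth configurable).

Both steps are translation-equivariant, so T shifts exactly with the data.
For a pure normal sample T ~ mu + 3 sigma and ~0.1-0.5% of cells are
flagged; across seeds the measured false-HP rate with no true HPs stays
below 2%.  Classification uses the final time point (62 h).  The
HP-specific productivity is the mean Delta I curve over HP-labelled cells
only.

Group statistics are delegated to scipy: Kruskal-Wallis (chi-square
approximation, mid-ranks, tie correction) for multi-group comparisons,
Wilcoxon rank-sum / Mann-Whitney (exact for small tie-free samples) for
pairwise ones, Anderson-Darling for normality screening.  The test suite
validates the rank-sum p value against exhaustive permutation on small
inputs.  No multiple-testing correction is applied, matching the source's
reporting of raw p values at alpha = 0.05.

A caveat recorded rather than resolved: the published per-condition HP
percentages (15.27/8.72/4.88%) are not exactly derivable from the
published per-chip counts (e.g. 17/163 = 10.4% and 38/223 = 17.0% for the
same condition); the presets carry the printed percentages, and per-chip
percentage followed by an across-chip mean is the implemented convention.

## Numerical and degenerate-input conventions

* Skewness at t = 0 is NaN by construction (Delta I(0) = 0 for every cell).
* r^2 of a zero-variance trace is 0; fits need >= 3 time points.
* The threshold needs >= 30 cells and positive spread; degenerate samples
  raise typed errors rather than returning a number.
* Probabilities and ratios validate their preconditions (non-negative
  lambda, integer k, positive volumes) and raise `InvalidInputError`.
* All randomness flows from one integer seed; per-frame streams are
  derived, never shared.

## Problem sizes

Unit and property tests run on chips of 16-1,600 anchors with 3-32 frames;
statistical operating characteristics (false-positive rate, power
monotonicity, skewness growth) are measured on trace-level simulations of
~400-600 cells per seed over 5-20 seeds, which gives binomial standard
errors comfortably below the asserted margins.  One end-to-end check runs
the full default chip (1495 anchors, 32 frames, 4.6 x 13 mm field at
1 um/px); it renders, segments and traces ~450 single-cell droplets in a
few minutes on one core.
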