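# Methods

This note documents the models, parameter choices and numerical conventions
behind `redoxhcs`, and what the synthetic data do and do not establish.

## Probe model and calibration

The dual-excitation probe is modelled as a two-state linear blend. A cell
whose probe pool has oxidized fraction *f* ∈ [0, 1] has expected emissions

    em405(f) = (1 − f)·a_red_405 + f·a_ox_405
    em488(f) = (1 − f)·a_red_488 + f·a_ox_488

and ratio R(f) = em405/em488. The calibration invariants are that oxidation
raises the 405-excited emission (a_ox_405 > a_red_405) and lowers the
488-excited one (a_ox_488 < a_red_488); together they make R strictly
increasing in *f*, so the ratio is a monotone oxidation readout.

No instrument-specific coefficients are published for this assay, so the
default calibration is a stand-in constrained by the two reported anchors:
resting cells read a ratio of 0.5, and the treated/control ratio increase is
three-to-five-fold (typically three-to-four-fold, up to five-fold at late
time points). The defaults a_red = (1.0, 4.0), a_ox = (4.0, 1.8) give a
fully oxidized ratio of 2.22 (4.44-fold over baseline, inside the reported
envelope); the resting oxidized fraction f_baseline = 1/4.1 is the root of
R(f) = 0.5 (`ProbeCalibration.with_baseline_ratio` solves it by Brent's
method for any coefficient set). `oxidized_fraction_for_ratio` inverts R in
closed form.

## Synthetic field rendering

Nuclei are filled ellipses (radius mean 6 px, sd 1 px, mild elongation and
random orientation) placed by rejection sampling with a minimum
centre-to-centre spacing; small spacings force touching cells. Each cell's
mitochondrial signal occupies an elliptical halo around the nucleus
(`cyto_extent_px`, default 6 px), with:

- multiplicative speckle texture: a gamma(k = 4) field smoothed with a
  σ = 1 px Gaussian (mitochondria are filamentous, not iid pixels) on a
  diffuse floor of 0.3 — both channels share the texture, so the per-pixel
  ratio is exact;
- a radial falloff e^−(ρ−1)/0.8 outside the nucleus (perinuclear
  mitochondrial density) and a 0.6 relative weight over the nucleus itself
  (mitochondria above/below the nucleus project onto it in widefield);
- per-cell brightness, lognormal with CV 0.3 (clonal lines are fairly
  homogeneous but not identical).

Pixels contested by overlapping cells go to the cell whose normalized
elliptical radius is smaller. The nuclear channel renders only nuclei; the
TMRM channel scales the mitochondrial texture by the cell's TMRM level.

Camera model: expected counts = photon_scale × emission + background;
a pixel is Poisson(expected) + N(0, read_noise_sd), rounded and clipped to
the 16-bit range, so shot-noise variance equals the expected count.
Screening-mode defaults are photon_scale 60 counts per emission unit,
background 100 counts, read noise 3 counts — a dim, shot-noise-dominated
EMCCD regime in which a resting cell's 405 channel is only ≈ 100 counts over
background (the hard case for intensity-based segmentation). Time-lapse
acquisitions are modelled brighter (photon_scale 150), reflecting the longer
exposures practical when imaging a single position instead of a whole plate
in 15 minutes.

Determinism: every generator output is a pure function of its spec and a
seed. Substreams (geometry, texture, biology sampling, camera noise,
per-field, per-trajectory, flow) are derived from the master seed with fixed
`SeedSequence` spawn keys, so per-cell texture never depends on the oxidized
fractions — raising one cell's *f* rescales its emissions without moving a
pixel, which is what makes the monotonicity property testable.

## Segmentation

**Intensity mode** thresholds the background-corrected ex405 image (Otsu by
default; a fixed threshold is available for reproducibility studies), drops
8-connected components smaller than `min_object_area_px` (default 50 px) and
labels the rest. Otsu on a 256-bin histogram makes the mask invariant to
multiplying the image by any positive constant.

**Nuclear-ring mode** thresholds the nuclear-marker channel, fills holes,
splits touching nuclei by a watershed on the negated Euclidean distance
transform seeded at local maxima at least `split_min_peak_distance_px`
(default 7 px) apart, and removes small objects. Ring ROIs are then built
per nucleus: erode the nucleus by `nucleus_erosion_px` (default 0), admit
every pixel whose *exact* Euclidean distance to the eroded seed is ≤
`ring_dilation_width_px` (default 6 px), and remove all nucleus pixels.
Contested pixels belong to the nearest seed, ties to the lower label. Using
per-pixel distances (via the exact EDT) rather than iterated
structuring-element dilation makes the construction identical to a
brute-force enumeration, which the test suite exploits as an oracle, and
makes results bit-reproducible.

Background correction subtracts a reference image when one is provided
(clamped at zero), else a robust scalar: the median of pixels below the
image's Otsu threshold.

The vendor vocabulary of the original assay ("polygon band", "erosion
factor") is not publicly specified; the ring construction above is this
package's documented reinterpretation of a perinuclear readout band.

## Quantification

The ratio image is per-pixel ex405/ex488 where ex488 clears an intensity
floor (default 9 counts = 3 × read noise); other pixels are masked, never 0
or ∞. The default per-cell ratio is the mean of per-pixel ratios over the
ROI's valid pixels; `ratio_mode="roi_mean"` (ratio of summed intensities) is
available and is the brightness-weighted alternative. In a
Poisson-dominated regime the pixel-mean estimator carries a small convexity
bias (E[x/y] > λx/λy, roughly R/λ488 per pixel); at screening exposure this
is ~1–3% for typical cells and the ≥200-cell median recovery error stays
under 5%, while the roi_mean estimator is essentially unbiased but weights
bright mitochondria more. Granularity is the coefficient of variation of
ex488 intensities within the ROI (population sd / mean; 0 for a uniform
ROI). Well summaries aggregate per-cell ratios (cell-averaged by default);
the high-ratio gate defaults to negative-control mean + 3 sd recomputed per
plate. Correlation is Pearson's r; zero variance raises an error rather than
returning 0.

## Screening statistics

Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| with sample standard deviations, computed
over per-well ratio means — wells are the replicate unit (per-cell values
can be fed in for exploration, but per-cell dispersion mixes biology with
segmentation noise). Fold change is well mean / cell-count-weighted pooled
negative-control mean; the default hit threshold of 3 matches the typical
reported effect size. Z′ is affine-invariant and strictly decreasing in
either arm's sd; identical arm means raise an undefined-separation error.

`zprime_comparison_study` freezes the segmentation-comparison experiment:

- **crowded plates**: 10 mock + 10 treated wells, one 256×256 field of a
  dense monolayer (70 cells, 12 px spacing — nuclei nearly touching);
- **sparse plates**: 16 + 16 wells, two fields of 25 well-separated cells
  (40 px spacing), so each plate's Z′ pair is tightly estimated;
- the treated arm is a moderate response (oxidized fraction Beta with mean
  0.55, sd 0.08, ratio ≈ 0.95). A maximal dose separates the arms so far
  that both modes score Z′ > 0.9 and the comparison is uninformative; the
  moderate window (Z′ ≈ 0.7–0.85) is where segmentation quality visibly
  moves Z′, consistent with the windows reported for the real assay.

On crowded plates intensity-only segmentation merges neighbours into a few
blobs per field; the nuclear-ring mode keeps one ROI per cell and yields the
higher Z′ essentially always (sign test across 12 replicate plates). On
sparse plates both modes segment every cell and their Z′ values agree to
within ≈ 0.04.

## Single-cell kinetics

Tracking is greedy nearest-neighbour centroid linking with a displacement
cap (default 5 px/frame), no gap closing and no division handling — dying
adherent cells drift slowly and do not divide. Trajectories are per-frame
mean valid-pixel ratios (and TMRM means) over the track's ring ROI.

The biphasic ratio course — baseline ≈ 0.4, a pre-permeabilization surge to
≈ 0.65, a ramp to ≈ 1.2 during reporter release and a drastic post-release
rise — is fitted as a piecewise-constant model with 0, 1 or 2 change points
by exhaustive least squares; segment levels are segment means, and the model
order is chosen by BIC = n·ln(RSS/n) + (2m+1)·ln n. The RSS is floored at a
tiny multiple of the squared data range, so noiseless fits are defined and
the selected change points are invariant to affine rescaling of the
trajectory. Ties break toward the earliest change points;
`min_segment_len` defaults to 3 frames. Piecewise-constant segments are the
simplest model that captures "surge then drastic increase"; fitting ramps is
a possible extension.

Event ordering: t_TMRM is the first frame TMRM stays at or below half its
baseline level, t_ratio the first frame the ratio stays at or above baseline
mean + 3 sd (baseline = first 5 frames); both gates require 2 consecutive
frames (a debounce — with only 5 baseline frames the sd estimate is noisy
and single-frame crossings fire early), and the reported crossing is the
first frame of the sustained run. The lag t_ratio − t_TMRM is positive when
membrane-potential loss precedes the redox rise, as the generator's default
kinetics (TMRM half-loss at frame 12, surge at frame 20, trajectory noise sd
0.02 ≈ 5% of baseline) encode.

## Flow-style analysis

Event tables are lognormal mixtures (per-population medians equal the stated
means; sd is the log-space sigma) with ground-truth population ids.
Per-event ratio is plain i405/i488 with an intensity floor; quadrant gating
partitions included events by a ratio and a marker threshold (default ratio
gate: control mean + 3 sd). No spectral compensation is modelled — a single
fluorophore excited at two lines needs none for its own ratio.

## What the synthetic data do not show

The generator reproduces the assay's structure (dual-excitation ratiometry,
perinuclear readout, crowding, camera noise, biphasic kinetics, event
ordering), not its full optics or biology: there is no PSF blur or
out-of-focus light, no cell motility beyond rigid drift, no shape changes or
detachment during death, no photobleaching, and the probe model is a
two-state blend without pH sensitivity or response-time lag. Passing tests
establish that the *pipeline* recovers known ground truth under realistic
noise and crowding, and that the qualitative directions reported for the
real assay (nuclear seeding improves Z′ on crowded plates; TMRM loss
precedes the redox rise; oxidation and death markers co-gate) emerge from
the stated mechanisms — not that the specific numeric results of any wet-lab
experiment are reproduced.

## Problem sizes

Default test and reproduction runs use 128–256 px fields, 8–96 wells with
one or two fields each, ≥ 200 cells for recovery statistics, 12 replicate
plates for the Z′ direction study, 200 replicates for change-point
localization and 10,000 flow events — sizes at which every reported
statistic is stable across seeds on a single CPU in about a minute.
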