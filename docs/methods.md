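# Methods

This note documents the models, conventions and design choices behind
`pulseratchet`: what each pipeline stage computes, what the synthetic-data
generator does and does not emulate, and where genuinely open choices were
resolved.

## Per-cell trace analysis

**Input model.** A cell trace is a strictly increasing time grid (seconds)
with apical area in μm²; NaN marks frames where segmentation failed.
Optional channels carry a fluorescent-reporter intensity (a.u.) and a shape
anisotropy.

**Gap handling.** Interior missing runs of at most `max_gap = 2` frames
(i.e. gaps smaller than three time points) are linearly interpolated
between the flanking measurements; longer runs stay missing. Leading and
trailing missing frames have no anchor on one side and are trimmed rather
than extrapolated.

**Smoothing.** All smoothing is a centered moving mean. The output length
equals the input length: near the boundaries the window is truncated
symmetrically (no padding), so boundary values are means over shorter,
centered windows. For even windows the interior window extends one extra
sample to the right; the analysis windows actually used are 3 points (for
displayed area) and 10 points (for displayed rates), i.e. roughly 11 s and
38 s at the default 3.8 s sampling.

**Constriction rate.** `rate_i = −(A_{i+1} − A_i)/(t_{i+1} − t_i) · 60`,
assigned to the interval midpoint. The sign convention makes constriction
positive. A literal area-over-time quotient has no pulsatile structure and
the wrong units; the difference quotient is the only reading consistent
with rates in μm²/min and with control cells having positive rates
throughout. Pulse detection always runs on the *unsmoothed* rate.

**Pulse detection.** Strict local extrema: a sample counts if it exceeds
both neighbors. A flat-topped run strictly above both flanks reports its
first sample (deterministic tie-break, mirroring MATLAB `findpeaks`);
endpoints are never extrema. Rate peaks with non-positive values are
discarded, for both polarities (expansion is the negated rate).

**Ratchet statistic.** The area trace is detrended with a least-squares
cubic; maxima and minima are located on the residual; for each extremum
kind the mean of consecutive differences is computed and the two kind-means
are averaged, expressed as % of the initial area. The differences are
evaluated on the **raw** area at the extremum indices (default): the
statistic is meant to capture the incremental area loss per pulsation
interval, which lives partly in the trend that the detrending removed.
Locating peaks on the residual while differencing the raw signal keeps
peak positions robust to the monotone decline yet preserves the decline in
the statistic. A `diff_on_raw=False` flag switches to pure-residual
differences (which by construction average ≈ 0 for any trace, useful as a
negative control).

**Categorization.** The ratio of the 3-point-smoothed area at the sample
nearest 420 s to the smoothed initial area assigns: < 0.5 constricted,
0.5–1 impaired (inclusive at both boundaries, matching the interval
notation "< 0.5; 0.5 < 1; > 1"), > 1 expanded. Cells not tracked through
the evaluation time raise instead of guessing.

**Track-length exclusion.** Cells tracked for less than
(median − 1 SD) of the cohort's tracked durations are excluded from
cohort-level outputs. The underlying rule as stated in the field's methods
texts is ambiguous ("tractable for only one standard deviation less than
the median"); we read it as a duration cutoff at median − 1·SD, with SD on
the n−1 denominator, and report every exclusion.

**Peak-triggered averaging.** Windows of ±25 s are extracted around
*isolated* peaks — no same-polarity peak within the half window — on a
common lag grid (linear interpolation in time); windows that would cross a
trace boundary are dropped, not padded. Mean and SD per lag are reported
over all collected windows for area, unsmoothed rate, and intensity.

**Two-stage averaging.** Cohort time courses average cells within embryo
first, then embryos; the displayed SD is across embryo means (n−1).

## Group statistics

Cohen's d uses the conservative denominator 2·s_max, where s_max is the
maximal sample SD (n−1) over all groups of the complete dataset; |d| < 0.5
is flagged not significant. This intentionally differs from the textbook
pooled-SD d — with hundreds of cells per group p-values saturate, and the
maximal-SD variant under-states rather than over-states effects. The
t-test is the classic pooled-variance two-sample test; ANOVA is the
standard between/within decomposition with a Tukey(-Kramer) post hoc at
α = 0.05 (statsmodels). Fold changes divide a group's mean rate by the
control-group mean; report tables round folds to one decimal and percent
changes to integers.

## Synthetic data

**Pulse waveform.** Each pulse is a raised-cosine constriction of amplitude
A over T_c seconds followed by a raised-cosine relaxation that recovers
(1 − e)·A over T_r seconds, where e ∈ [0, 1] is the ratchet efficiency;
the permanent plateau sits at −e·A per completed pulse. The waveform is
smooth, has zero slope at phase boundaries (so rate peaks are clean and
unambiguous), and makes the bookkeeping exact: after k pulses the retained
loss is k·e·A. No waveform is prescribed by the phenomenology this
emulates; the raised cosine is the simplest shape with these properties.
Only pulses that complete within the trace are emitted.

**Sampling.** Default dt = 3.8 s (a 10-point smoothing window spanning
~38 s pins the frame interval); pulse periods are drawn per cell from
60–90 s; the first pulse starts at U(5 s, period) so the initial sample is
a clean pre-pulse baseline. Per-cell random streams derive from
`SeedSequence([seed, embryo_index, cell_index])`, so cohorts are
reproducible cell-by-cell.

**Cohort calibration.** Cohorts draw, per cell, target *measured* peak
constriction and expansion rates from class-specific normal distributions
(control-like: 9.9 ± 1.1 and 3.2 ± 0.8 μm²/min; deficient:
7.5 ± 1.2 and 5.1 ± 1.4 μm²/min), a target area ratio at 420 s from a
class band, an initial area (36 ± 3 μm²), and a pulse period. The
generator then solves for the waveform: the amplitude is the drawn rate
divided by the *expected discrete-sampled* peak rate of a unit raised
cosine (tabulated by averaging the maximum finite-difference quotient over
the sampling phase), the relaxation duration is found by inverting the
same table for the expansion target, and a linear trend slope is fixed so
the noise-free area at 420 s lands exactly on the target ratio
(fixed-point iteration over the weak amplitude–slope coupling). The trend
additionally carries a tiny quadratic term (rate drift 10⁻⁴ μm²/min per
second) so the between-pulse baseline rate is strictly monotone: a
constant-to-rounding plateau would otherwise sprout rounding-level strict
extrema that the prominence-free peak detector picks up. Class counts are
assigned by largest-remainder rounding, so printed mixtures (e.g. 50/44/6%
of 300 → 150/132/18) reproduce exactly at any n.

**Measurement noise** defaults to zero. The per-cell rate targets already
carry the printed cell-to-cell group SDs, which is the variability the
group statistics rest on; frame-to-frame area noise is a separate nuisance
that the prominence-free peak detector is deliberately sensitive to (every
positive wiggle is a peak), and is left configurable for robustness
studies rather than baked into the study conditions.

**What the generator does not emulate:** viscoelastic tissue mechanics,
neighbor coupling between cells, myosin flows, photon statistics (camera
noise is plain Gaussian, optics plain Gaussian blur). Passing tests
therefore validate the *analysis pipeline* against known ground truth;
they do not certify biological realism of any particular trace.

**Surface phantoms** place a bright band of configurable thickness centered
on an analytic height field (flat, tilted plane, sinusoid, paraboloid)
with fractional-overlap slice weights and a 1% apodization toward the band
center, so the brightest slice of a column is always the slice nearest the
true height (no argmax ties). **Labeled movies** lay cells out on a grid of
bounding boxes and fill exactly the prescribed pixel count per frame, so
label areas are exact and mean intensities recover the prescription.

## Surface projection

Grid units default to 16 px with a height-map Gaussian of 1 grid unit and
a projection thickness of 3 slices (none of these is prescribed; they are
exposed as parameters). The per-unit z-profile is the sum of intensities
per slice, and its argmax (ties to the lowest z, i.e. most apical slice)
is the raw height. "Projected proportionally" is implemented as
fractional-overlap weights of each slice against a fixed-thickness band
centered at the filtered, fractional height. The anti-grid-artifact pass
pads each slice by half a grid unit, fills the padding with the mean of
that slice's outer margin (half a grid unit wide), recomputes everything
on the offset grid, and averages the two projections pixelwise. On a flat
phantom with matched band/projection thickness the algorithm is exact for
any grid size dividing the image.

Note that a projection window equal in thickness to the phantom's band
necessarily loses edge-slice intensity at fractional heights; fixtures that
check projected *intensity* therefore use a band thicker than the window.

## Image conventions

z index 0 is the first plane of the stack. The lowest-plane background
rule reads plane 0; the apical mean projection reads the first
`round(depth/z_step)` planes. Background subtraction clamps at zero
(negative intensities are non-physical). Anisotropy is the square root of
the ratio of second moments along the anteroposterior vs dorsoventral
image axes, with the +1/12 unit-square pixel correction so a w×h rectangle
scores exactly w/h; transposing the label image inverts it exactly.

## Numerical choices and degenerate inputs

- Detrending requires ≥ 5 measured samples; rates require ≥ 2 and a
  max/min sampling-interval ratio < 2.
- The ratchet statistic requires ≥ 2 maxima or ≥ 2 minima; cells without
  enough pulses raise and are skipped by the model layer, as are cells
  without rate peaks of a polarity (they drop out of that statistic).
- Zero-variance inputs to t/ANOVA/effect-size raise explicit degenerate
  errors rather than returning NaN.
- All file writes are write-then-rename, so interrupted runs never leave
  half-written outputs.

## Problem sizes

The test suite exercises cohorts of 40–300 cells and stacks up to
16×64×64 voxels; the acceptance script uses two 200-cell cohorts for rate
recovery, a 368-cell and a 233-cell cohort for category fractions, five
25-cell cohorts for the ratchet sweep, five noisy 16×64×64 phantoms for
surface accuracy, and five 9-time-point synthetic optogenetic series.
These sizes give standard errors comfortably inside the tolerances checked
(e.g. ±0.3 μm²/min on group mean rates at n = 200) while the whole suite
runs in well under a minute.

## Known limitations

- The ratchet statistic's absolute scale depends on the trend and pulse
  period of the input; only its sign and ordering across conditions are
  interpreted.
- The "isolated peak" rule for triggered averaging (no same-polarity peak
  within the half window) is one reasonable reading of an under-specified
  procedure; heavily pulsing cells contribute few isolated peaks.
- The surface projection assumes a single dominant bright sheet per grid
  unit; multi-layered structures will confuse the per-unit argmax.
- Cohen's d as implemented follows the maximal-SD formula literally; it is
  not comparable to textbook pooled-SD d values.
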