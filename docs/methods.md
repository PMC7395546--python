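# Methods

`erkpulse` analyzes pulsatile ERK activity in single cells measured by a
FRET biosensor. The activity readout is the dimensionless FRET/CFP ratio per
cell per frame; all analyses operate on tracked per-cell time series
(hours, ratio, optional x/y position and differentiation-reporter
intensity). This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## Synthetic trace model

Each simulated cell is a phenomenological pulse train, not a mechanistic
MAPK network model:

- **Sampling**: uniform grid, 5-min interval, 24 h duration (defaults).
- **Basal level**: constant FRET/CFP of 1.1 (realistic ratios sit near
  1.0–1.2).
- **Pulses**: event times form a renewal process with iid exponential gaps
  of mean 1/`pulse_rate_per_h` (default rate 1/1.52 h⁻¹), i.e. a Poisson
  process — pulses are stochastic, not oscillatory. Each event adds a
  raised-cosine bump of full width 0.25 h (smooth, compactly supported; the
  true waveform is unknown) and height `pulse_amplitude` (default 0.25 ratio
  units, a free parameter; only its largeness relative to noise is
  constrained). Overlapping bumps sum additively.
- **Noise**: iid Gaussian, sd 0.02 — an order of magnitude below the pulse
  amplitude, as "noise much smaller than pulses" requires.
- **Differentiation mode**: with `reporter_onset_model =
  "coupled_to_pulse_shutdown"`, no pulse events occur after
  `shutdown_time_h`, and the reporter rises from 0 as a saturating ramp
  `R_max (1 − e^{−(t−t_s)/τ})` (τ = 2 h, R_max = 100 a.u.). Only the onset
  timing is meaningful; the ramp shape is a modeling convenience.
- **Reproducibility**: every trace has its own generator; cohorts spawn
  per-trace `SeedSequence` children from the config seed.

Two finite-window facts matter when validating the generator:

- The pooled sample mean of gaps observed inside a window of length T is
  biased low: E ≈ μ(T − 2μ)/(T − μ) for exponential gaps of mean μ
  (≈ 1.42 h at μ = 1.52 h, T = 24 h). Tests against the configured mean use
  this closed form, or long windows where the bias vanishes.
- Gaps shorter than the pulse width merge into a single bump (below).

What the generator does **not** emulate: photobleaching and drift, basal
trends, amplitude heterogeneity between cells, tracking gaps and errors,
cell division and movement, or any feedback between reporter and ERK. Green
tests therefore establish correctness of the *metrics*, not robustness to
every artifact of real imaging data.

## Pulse detection

Pulses are local maxima of the ratio with a minimum topographic prominence
and a minimum peak-to-peak separation (`scipy.signal.find_peaks`
conventions; plateau tops count once, at their midpoint). Amplitude is the
prominence above the local baseline; duration is the full width at half
prominence (for the raised-cosine pulse this is half the full width, ≈
0.125 h); frequency is the peak count divided by the observed span (last
minus first time), since traces have unequal lengths. Traces with
non-uniform sampling are linearly interpolated onto their median interval
first, so 5- and 15-min acquisitions share one code path.

Defaults, and why:

- **No pre-smoothing** (`smoothing_window_min = 0`). At 5-min sampling a
  0.25 h pulse spans ~3 elevated samples; a 3-sample median filter flattens
  exactly such features and measurably destroys pulses (tens of percent of
  detected frequency). Smoothing remains available for noisier, sparser
  data.
- **Auto prominence = 5 × MAD of the first differences.** For iid Gaussian
  noise MAD(Δy) ≈ 0.954 σ, so the floor sits near 4.8 σ. This is chosen so
  that pulse-free negative-control traces (the biosensor-control condition)
  report essentially zero pulses (~0.05/h measured); a 3 σ-equivalent floor
  admits ~0.2 false pulses/h. The estimator is inflated by pulse slopes when
  pulses occupy much of the trace, making it conservative for densely
  pulsing cells — a known limitation.
- **Min separation 10 min** (2 frames): enough to avoid double-counting one
  pulse's plateau, while not discarding genuinely resolvable 10–15 min gaps.

**Resolution limit.** Two raised-cosine pulses of width w merge into a
single local maximum when their separation is below w/2 (= 0.125 h), and
the 5-min grid cannot represent peaks closer than 2 samples (0.167 h). With
exponential gaps a fraction 1 − e^{−rate·0.15} of intervals falls below
this limit: ~7% at 0.5/h, ~26% at 2/h. Detected frequency is therefore an
undercount that worsens with rate (measured bias ≈ −9% at 0.5/h, −20% at
1/h, −40% at 2/h, −70% at 3/h under the default study conditions), and
detected interval distributions are left-censored. This is a property of
*any* local-peak count on overlapping pulse trains, not of this
implementation; the moving variance (below) is the preferred pulse-level
measure precisely because it degrades gracefully under overlap. Interval
statistics intended to verify the exponential law are computed on generated
event times.

`fit_exponential` uses the exponential MLE (rate = 1/mean) and reports a
Kolmogorov–Smirnov statistic against Exp(rate). Classification gates: pulse
class "high" at ≥ 1.5 pulses/h; basal class "high" at mean ratio ≥ 1.2
FRET/CFP. Both boundaries resolve ties upward, deterministically.

## Variance metrics

- **Instantaneous variance**: sample variance (ddof = 1) of the ratio
  across all cells observed at a time point; points with fewer than 2 cells
  are omitted.
- **Moving variance**: per cell, sample variance in 50-min windows centered
  on each sample (maximally overlapping, stepped by one sampling interval).
  Windows are defined on time, not frame count; partial windows at the trace
  edges are dropped, and windows with fewer than 3 finite samples are
  skipped. The window is long enough to contain a typical 0.25 h pulse yet
  short enough that the window mean is effectively constant.
- **Pulse level**: the time-average of a cell's moving variance; zero for a
  constant trace, increasing with both pulse amplitude and count.

Numerical detail: window contents are shifted by their first sample before
`np.var`, which is algebraically a no-op (variance is shift-invariant) but
makes constant windows evaluate to exactly 0.0 even for levels that are not
binary-representable (e.g. 1.1). Sample variance (n−1) is used everywhere;
the choice is recorded here because population variance would change every
numeric output slightly.

## Phase diagrams

Per cell, the 50-min moving mean of the reporter (x) is paired with the
50-min moving variance — or moving mean — of ERK (y); only traces spanning
strictly more than 90 min are analyzed. The (x, y) plane is divided into a
regular 10×10 grid spanning [0, max] on each raw axis; each
consecutive-point displacement is assigned to the block containing its
*start* point (forward-difference reading), blocks are half-open with the
top edge closed, and the per-block arrow is the mean displacement. Arrows
are rescaled by the global axis maxima, x′ = x/max(reporter mean),
y′ = y/max(ERK variance), and converted to signed transition probabilities
r_x = x′/(|x′| + |y′|), r_y = y′/(|x′| + |y′|), so |r_x| + |r_y| = 1 in
every populated block; blocks with no segments or an exactly zero arrow are
flagged absent rather than given probabilities. Maxima are global over the
dataset, not per cell, so rescaling absorbs units and multiplying all
reporter intensities by a constant leaves r_x, r_y unchanged. The block
count and a minimum-segment threshold for drawing arrows are parameters;
the diagram is descriptive and no kinetic model is inferred from it.

## Spatial clustering (RDF)

g(r) = N(r, Δr)/N_ref(r, Δr), where N counts, over all reference cells,
the cells lying in the half-open ring [r − Δr/2, r + Δr/2); in a single
population each unordered pair contributes twice. N_ref is the same count
for uniformly random points in the field of interest, averaged over 20
realizations to suppress its own Monte-Carlo noise (a single random set
leaves ~5–10% noise in the denominator). Defaults: Δr = 10 μm (about one
cell diameter), ring centers 5–145 μm. Radii with N_ref = 0 are flagged
undefined, never divided.

The field of interest is the union of discs (dilation radius in μm) around
observed cells, as an exact polygon; restricting both the pattern and the
random references to it handles edge effects by construction, with no
analytic edge correction.

The null envelope comes from 50 CSR realizations at the observed point
count. The bounds are the rank-based envelope [min, max] of the 50
realizations — pointwise exceedance 2/(m+1) ≈ 3.9%, the conservative side
of a nominal 95% interval. (Interpolated 2.5/97.5 percentiles of 50 draws
cover only ~91% and systematically over-flag CSR patterns; this was
measured, and the rank envelope adopted, before freezing the defaults.)
Classification per radius: above/below the envelope means
clustered/dispersed for one population; for two marked populations (rings
around reference cells, counting target cells, envelope built by
randomizing target positions with references fixed) below/above means
segregated/grouped.

Synthetic point patterns: CSR, or a Thomas cluster process (uniform
parents, Gaussian offspring, sd 25 μm giving the ~50 μm cluster scale of
epidermal proliferative units). Marks are independent coin flips, or
spatially exclusive ("clustered_low_pulse": low-pulsing cells are the
cluster offspring, high-pulsing cells scatter uniformly outside a 2·sd
exclusion zone around cluster centers). Exclusivity matters: if the two
groups' positions are independent, the cross-RDF is 1 in expectation no
matter how clustered each group is, and no segregation exists to detect.

## Pipeline and reproducibility

`run_pipeline` executes the configured stages (simulate → ingest → detect →
variance → phase → rdf) in order and writes a manifest with the package
version, the full config, its hash, and a SHA-256 checksum of every output
file; identical config + seed reproduce identical checksums. The per-cell
summary combines the basal gate and the pulse class into four states
(Basal^{lo,mid,hi} × Pulse^{lo,hi}); the upper basal gate is 1.2 FRET/CFP,
and since only that gate is quantified, the lower gate defaults to the
cohort's 25th percentile of mean ratio (configurable).

## Problem sizes used in tests and acceptance runs

Cohorts of 40–60 traces (24 h, 5-min sampling), spatial patterns of
400–1400 points in a 1 mm² field, 50-realization envelopes, and 10–50
seeded repetitions per calibration check. These sizes put Monte-Carlo error
comfortably below the tolerances asserted while keeping the full suite in
the minutes range.

## Known limitations

- Detected pulse frequency undercounts at high rates (resolution-limited
  merging; see above). An unbiased rate estimate under censoring would be
  1/(mean detected gap − τ) by memorylessness, but the reported frequency
  is deliberately the plain count/span the classification gates are defined
  on.
- The auto-prominence calibration degrades when pulses dominate the trace.
- The RDF has no inhomogeneous-intensity correction (none is defined for
  this estimator); strong density gradients inside the field of interest
  will read as clustering.
- The reporter waveform and pulse amplitude distribution are conventions;
  conclusions that depend on their exact shapes should not be drawn from
  the synthetic cohorts.
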