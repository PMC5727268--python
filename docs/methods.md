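# Methods

## Signal path

A recording is a continuous EMG channel (µV) plus a synchronized stimulus
trigger channel at a common sampling rate (2 kHz default).  Trigger onsets
are rising-edge crossings of the level `min + 0.5·(max − min)`, debounced
two ways: a crossing must persist for ≥ 2 samples (rejects single-sample
noise spikes while keeping 1 ms rectangular pulses at 2 kHz), and later
crossings within a 200 ms refractory period are suppressed (absorbs edge
chatter; 200 ms sits far below the ~1 s interstimulus interval and far
above the 500 µs pulse width).

Epochs span [−5, 20) ms around each trigger, half-open, with floor-based
millisecond-to-sample mapping and 0-based indexing; at 2 kHz each epoch is
50 samples with the trigger at sample 10.  Trigger-to-train assignment is
purely positional — the protocol always stimulates the five intensities in
ascending order within a train — with the observed inter-train gaps logged
as a sanity check but never used for grouping.  Epochs that would cross a
recording edge are dropped with a warning, never padded; averaging proceeds
if at least one train survives per intensity, and `n_averaged` is recorded.

The amplitude feature is the peak-to-peak voltage (Vpp) over the
[1, 15) ms post-stimulus window, computed **after** subtracting the
pre-stimulus mean (−5..0 ms).  The baseline subtraction is a deliberate
choice: it makes Vpp exactly invariant to DC offset and slow drift.
Waveforms are grand-averaged across the four trains *before* Vpp
extraction.  The order matters because max − min is nonlinear: averaging
per-train Vpp values keeps the full single-epoch noise bias (the expected
range of pure noise is strictly positive), whereas waveform averaging first
halves the noise floor at four trains.  A regression test pins this order.

## Normalization and the linear model

With intensities P1..P5 (100–140 %MT), the model is fitted on percent
scales: `x[n] = (P_n − P_1)/P_5·100` and either the baseline-based response
`y[n] = (C_n^x − C_1^x)/C_5^0·100` or the per-trial response
`y[n] = (C_n^x − C_1^x)/C_5^x·100`.  Both force `y[1] = 0`; they coincide
exactly on the initial condition.  Per-trial normalization is invariant
under any uniform rescaling of a condition's amplitudes, so it can detect
injury only through a change of recruitment-curve *shape* — this is the
property that makes baseline-free monitoring possible, and also its blind
spot (see the simulator's trap configuration below).  The line is fitted by
plain OLS on the design `[1, x]`; parameters are carried in named fields
(slope `a`, intercept `b`) to keep the ordering unambiguous, and the
residual sum of squares rides along as a diagnostic.  Fitting against the
raw %MT ladder instead of the normalized x is available as a flag for
comparison.  A vanished normalizing response (C_5 = 0) raises a dedicated
`NonConductingError` so pipelines record the condition as non-conducting
instead of fitting garbage; such conditions are excluded from fits and
paired tests and reported separately.

## Protocol encodings

The load-cell calibration is affine, `force(g) = 0.6556·x + 2.7617` for
digital reading x, from a bench calibration of the compression tool.
Graded damage levels are fractions of the maximum tolerated level (the
level at which the CMAP at 140 %MT disappears); the default fractions
(1/3, 2/3, 1) reproduce the 30/60/90 g compression ladder.  A variant with
the middle level at half maximum is selectable — the two conventions both
appear in practice and the package does not privilege the inconsistent one.
The motor-threshold search is a computational surrogate for the visual
twitch criterion: the lowest tested intensity whose Vpp exceeds k·(noise
SD), k = 3 by default.  Incision extent is quantified from grayscale
images: both images are binarized with a single Otsu threshold computed on
the *baseline* image (an explicit override and a rectangular ROI are
available) and the loss of white pixels relative to baseline is reported as
a percentage, clipped to [0, 100].  Sharing the baseline threshold keeps
the measure monotone in pixels removed and well-defined for a fully
blacked-out incision, where per-image Otsu would be degenerate.

## Synthetic cohort

The generator emulates the study conditions: 16 nerves, 4 conditions each
(initial + three graded damage levels), 4 trains of 5 ascending intensities
at 100–140 %MT, 1 s ISI, 5 s between trains, 2 kHz sampling.

Each nerve is a population of 200 motor axons with lognormal recruitment
thresholds (median 1.0 MT, σ = 0.25 — the experimental window then samples
the rising mid-segment of the recruitment sigmoid) and lognormal unit
amplitudes (median 3 µV, σ = 0.5; ~600 µV summed CMAP at saturation,
a plausible magnitude for needle-recorded gastrocnemius CMAPs).  Lognormals
are the standard positive-support, right-skewed choice for motor-unit
properties.  The noiseless amplitude at intensity P is the summed unit
amplitude of conducting axons with threshold ≤ P.

**Injury model.**  Damage is graded conduction block: fractions
(0, 0.15, 0.45, 0.75) of axons stop conducting at levels 0..3, with blocks
nested across levels.  By default the block is applied in *descending
threshold order* — the axons recruited last are lost first — which caps the
recruitment curve at a damage-dependent ceiling and flattens the
100–140 %MT segment.  This choice is forced by the mathematics of the
per-trial normalization.  For any log-concave threshold distribution F and
a multiplicative threshold elevation s, the self-normalized span
`1 − F(P1/s)/F(P5/s)` is *increasing* in s (the ratio φ/Φ is decreasing, so
`d/d ln s · ln[F(P1/s)/F(P5/s)] = [φ5/Φ5 − φ1/Φ1]/σ < 0`): uniform
threshold elevation alone *steepens* the self-normalized curve rather than
flattening it, and uniform random block rescales the curve and cancels out
of the normalization entirely.  Only a shape change — preferential loss of
high-threshold axons — reproduces the observed monotone slope decline in
both normalization modes while also reaching "no response at 140 %MT" as
the block approaches 1.  A multiplicative `threshold_shift` per level is
retained as an optional field (default 1.0) for experimentation.

The trap configuration `InjuryModel(block_order="random")` makes the
blocked subset independent of threshold: the expected recruitment curve
scales uniformly, per-trial slopes become statistically indistinguishable
across damage levels, and a test asserts both halves (median |Δa| under the
trap collapses below one third of the default separation).  This
demonstrates what a passing per-trial classifier does and does not show:
it detects recruitment-shape change, not amplitude loss per se.

Amplitude noise (SD 15 µV, Gaussian, truncated so Vpp ≥ 0) is applied at
the Vpp level when amplitude rows are generated directly — representing
residual post-averaging measurement error — and as white sample noise when
full recordings are synthesized.  Synthetic recordings place a biphasic
template (3 ms latency, 2 ms positive / 3 ms negative lobes, 60/40
amplitude split, renormalized to unit peak-to-peak after sampling) scaled
to the noiseless recruitment amplitude at each programmed trigger, with
rectangular trigger pulses; ground truth (trigger indices, programmed
amplitudes) rides in `meta`.  Inter-subject variability jitters the
population hyperparameters lognormally (5 % threshold median, 10 %
threshold spread, 20 % unit amplitude, 20 % motor threshold); the absolute
MT cancels out of the %MT ladder by design.  All randomness derives from
explicit integer seeds; axon draw and block assignment depend only on the
nerve seed (conditions of one nerve are paired), while noise streams are
level-specific.

What the simulator does **not** model: conduction-velocity dispersion and
latency shifts, stimulus artifacts, probe-position variability,
non-stationary noise, and any biophysics of compression vs incision (both
reduce to graded block).  Passing tests therefore show the *method* behaves
as designed under its stated assumptions, not that real surgical recordings
will separate this cleanly.

## Classification and statistics

Conditions {initial, damage1} are labeled healthy, {damage2, damage3}
injured; a 16-nerve cohort gives 32/32 points.  Splits are deterministic
for a seed, with train size `floor(0.7·N)` (44/20 at N = 64) and
stratification by label on by default — plain random splitting is available
but degenerate test sets at this N are a real risk.  The classifier is a
linear-kernel soft-margin SVM, C = 1, on raw (a, b) without standardization
(the boundary then lives in the same coordinates as the parameter scatter);
an upstream scaler can be applied where a and b ranges differ wildly.  A
point exactly on the boundary is called healthy — the alarm fires only on
strictly positive evidence of injury; the tie rule is arbitrary but
documented and tested.  The transfer evaluation trains the boundary on
baseline-normalized points (70 % split) and applies it unchanged to the
per-trial points of all subjects, reporting per-condition accuracies; on
the default cohort the intermediate damage2 condition transfers worst,
mirroring the expected boundary-condition difficulty.  Accuracies are
reported as exact fractions and rounded to one decimal for display.

Condition contrasts use two-sided paired t-tests on per-subject parameter
differences (every nerve is its own control), with no multiple-comparison
correction by default, matching the study design this package re-implements;
a Bonferroni adjustment can be applied downstream from the exact p values in
`comparisons.csv`.  Zero-variance differences are handled explicitly
(all-zero → t = 0, p = 1; constant nonzero → ±∞, p = 0, flagged).

## Numerical and I/O choices

* CSV recordings (`time_s,emg_uV,trigger`) round-trip losslessly; the
  sampling rate is inferred from the time column only if uniform within
  1 ppm.  EDF files are read through `mne`; the package writes EDF with its
  own minimal writer (1 s records, int16, physical range set to the data
  range), so EDF round-trips are exact to the 16-bit quantization step,
  about `range/65535`.
* Amplifier gain (1000 in the reference chain) is divided out on request so
  samples are µV at the electrode; it is recorded in `meta`.
* Problem sizes in the test suite are chosen to keep the full scientific
  checks cheap: 1000 random instances for the OLS oracle equivalence (with
  a 1e-3 grid search on a 20-instance subsample, windowed around the
  closed-form solution), 100 simulated recordings for amplitude recovery,
  500 seeds for the block-fraction expectation, 24 for the trap comparison.
  The 5 % recovery criterion is evaluated as the mean relative error across
  the 100 noisy recordings; single epochs at the lowest intensity can reach
  ~9 % by noise alone, which is expected for a max−min statistic at this
  SNR.

## Known limitations

* The linear model is only sensible over the narrow 100–140 %MT window; no
  sigmoidal fitting is attempted, by design.
* The per-trial mode is provably blind to uniform amplitude loss; it is a
  shape detector.  Clinical use would pair it with an absolute
  response-present check (the `NonConductingError` pathway).
* The healthy/injured dichotomy discards the 4-level grading; multiclass
  classification is out of scope.
* Motor-threshold determination is a surrogate; the package assumes a
  single initial MT per nerve, not re-determined after each damage level.
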