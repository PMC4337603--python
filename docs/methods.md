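# Methods notes

This note documents the models, numerical choices, and deliberate design
decisions behind `avcoherence`, and what the simulated data do and do not
establish about real behavior.

## Envelope synthesis

Envelopes are synthesized in the frequency domain at the requested
sampling rate: every rFFT bin with frequency strictly inside (0, cutoff)
receives unit magnitude and an i.i.d. uniform phase in [0, 2π); DC, the
Nyquist bin, and everything at or above the cutoff are zero. The inverse
real FFT enforces Hermitian symmetry, so the output is exactly real and
exactly band-limited. Default cutoff is 7 Hz, the modulation range of
speech envelopes and mouth movements; a 14 s trial at this cutoff carries
97 nonzero components, making the envelope an effectively Gaussian
band-limited noise.

Per trial, three envelopes are drawn and orthogonalized by classical
Gram–Schmidt: the first is the reference and is untouched; the second and
third have projections removed in order. Inner products are plain
unweighted dot products over the full trial (the DC bin is already zero,
so no mean removal is needed). Orthogonalized envelopes are *not*
re-normalized to unit norm: the subsequent affine rescale to [0, 1] makes
any such scaling immaterial. Each envelope is then independently mapped
to [0, 1] (min/max affine) and accentuated pointwise by y = sin²(πx/2),
which fixes 0, ½, and 1 and steepens the extremes. Orthogonality is
therefore a property of the pre-normalization signals; the affine offset
and the pointwise nonlinearity intentionally destroy exact orthogonality
of the final envelopes, as in the original construction. Band limits are
asserted through the normalization stage only — accentuation, being a
pointwise nonlinearity, spreads harmonics of in-band components above the
cutoff by design.

The visual envelope subsamples the auditory one at the monitor frame rate
(60 fps): frame k takes the audio sample at index ⌊k·rate/fps⌋ (frame 0 =
sample 0), and the frame count is ⌊duration·fps⌋ (840 frames for 14 s).

## Stream synthesis

**Pitch streams.** An event's carrier deflection is one full sinusoid
period, peak ±1.5 semitones over 100 ms (semitone ratio 2^(n/12)). The
instantaneous frequency f₀·2^(offset(t)/12) is integrated by cumulative
sum at the sample rate into the phase, guaranteeing phase continuity
through events; the measured peak excursion of the synthesized waveform
(analytic-signal phase differentiation) reproduces 1.5 semitones to
better than 0.1%. Amplitude is the accentuated envelope times a level
scale; the 565 Hz stream carries −3 dB (applied pre-mixing, i.e., to the
modulated stream — the construction makes pre- vs post-modulation
equivalent since the envelope is shared).

**Timbre streams.** The source is a periodic impulse train (pulses at the
nearest sample to every k/F0); the filter is a cascade of four two-pole
resonators, one per formant. Pole radius is exp(−πB/fs) with 3-dB
bandwidths (60, 90, 150, 200) Hz for F1–F4 — conventional vowel-synthesis
values; the reference design does not state bandwidths, so they are
config-exposed. Each resonator is normalized to unit gain *at its center
frequency* rather than at DC: with DC normalization, the upward F1
excursion of the /u/ deviant raises the cascade gain ~25% even at the
default morph fraction, which would break both the unit-peak bound and
exact event locality. With peak-gain normalization the cascade's resonance
positions are unchanged (the lowest /u/ peak sits at 459.9 Hz on a fine
grid) and stream level is stable through events.

During an event, F1 and F2 move linearly to steady + fraction·(deviant −
steady) over 100 ms and return linearly over the next 100 ms (F3/F4 are
fixed); the default fraction 0.1225 is the average perceptual threshold
for the original task and is per-run configurable. Filter coefficients
are recomputed per sample inside event windows with filter state carried
across updates (morphs are slow relative to resonator ring time, and
per-sample updates avoid block-boundary artifacts); the steady spans
between events run through `scipy.signal.lfilter` with carried state, so
a stream with events is bit-compatible with its no-event twin outside the
event windows plus ring-out. Stream level is referenced to the
steady-state-filtered carrier's peak with a fixed 0.8 headroom factor
(worst-case transient gain rise during a full-fraction morph is ~1.21×).

**Mixing.** Both streams get 10 ms raised-cosine onset/offset ramps. The
masker is gated to exactly zero before its 1 s delay and ramps in with a
fresh 10 ms raised cosine at the delay (ramps are per-stream, not applied
to the mixture). Optional stationary white background noise is scaled
relative to the target stream's RMS (−24 dB for the pitch task's booth
noise, −11 dB for the timbre task's, both config-exposed; absolute SPL
calibration is out of scope — levels are relative throughout). The
mixture is identical in both ears by construction (a single channel is
the contract); it is rescaled only if its peak would exceed 1, and the
scale is recorded.

**Visual stream.** The contract is parametric: per-frame disc radius
(affine map of the envelope to 1°–2.5° of visual angle, ring width
0.125°, viewing distance 50 cm recorded as metadata) and a per-frame
flash flag. A flash turns the ring cyan for 100 ms — exactly six frames
at 60 fps, because a half-open interval of exactly six frame periods
always contains six frame starts. Pixel rendering is deliberately not
implemented.

## Scheduling

Event counts per trial are uniform on {1, 2, 3} for target and masker and
uniform on {0, 1, 2} for flashes — the maximum-entropy laws matching the
stated supports and means (2, 2, 1). Onsets live on a 1 ms grid restricted
to [2 s, 13 s − duration] and to times where *both* auditory envelopes
are at or above 75% of their own maxima (the gate applies to flashes too);
all onsets must be pairwise ≥ 1.2 s apart, which makes the 1 s response
windows provably disjoint. The 1.2 s separation is between onsets, and
the gate is evaluated at the onset sample only.

The feasible set under these constraints is genuinely small: the joint
75% gate admits ~3% of the grid on average, and about 40% of
(envelope-triplet, counts) draws cannot host the drawn events at all —
maximal 8-event trials almost never fit a single triplet. The sampler
therefore (a) places events sequentially, drawing uniformly from the
candidates still compatible with the separation constraint (the
conditional law of accepted rejection draws, so schedules remain uniform
over the feasible set), (b) restarts the whole placement on dead ends,
(c) rejects truly infeasible draws immediately via an exact greedy
max-packing bound, and (d) on an unschedulable trial the session builder
regenerates the envelopes with a fresh recorded seed, keeping the drawn
counts — so realized event-count statistics match the count law exactly.
Regenerations average ~3 per trial and are logged on the trial record.

Sessions are n trials per condition (32 by default, 96 total) in a
uniformly random order with no blocking; every trial stores its envelope
seed, so sessions replay bit-identically without storing sample data.

For scheduling-only work (scheduler tests, observer cohorts, the
session-level event-total estimates), envelopes are generated at 1–2 kHz
rather than 24,414 Hz: the scheduler reads the envelope only through its
values on the 1 ms candidate grid, and the envelope's statistics are
independent of sampling rate, so this is purely a problem-size choice.
Stimulus rendering always uses the full audio rate.

## Simulated observers

The observer model targets the *statistical structure* of the behavioral
data, not any sensory mechanism: per target event a press occurs with
probability (1 − lapse)·p_hit[condition] at a uniform latency on
(0.15, 0.9] s (support inside the 1 s window keeps intended hits
attributable; no latency data exist for the original task), per masker
event with (1 − lapse)·p_fa[condition], per flash with p_visual_hit, plus
an optional Poisson process of spontaneous presses (default rate 0, since
unattributed responses were rare in the original task and are not
analyzed). A single button serves all event types; attribution is purely
temporal and unambiguous given disjoint windows.

Cohort generation converts per-condition generating d′ and a criterion c
to probabilities via the equal-variance model hr = Φ(d′/2 − c),
far = Φ(−d′/2 − c) (clipped to (0.01, 0.99)), with normal between-subject
jitter on both (SD 0.35 in d′, shared across conditions; SD 0.2 on c).
The shipped `reference_profile` (pitch d′ 2.4/2.15/1.9 for
match-target/neither/masker, timbre 0.85 lower, c = 0.5, visual hit
probability 0.877) encodes only the *direction and rough size* of the
reported effects and the reported overall visual hit rate; it is
configuration for demos and power analyses, not an empirical claim.
`null_profile` equalizes all cells for calibration studies. A
counts-level generator (binomial draws per subject×condition, skipping
scheduling and timing) provides fast replicates for Monte-Carlo
calibration; it shares the parameter-draw path with the full simulator.

What passing tests show: the pipeline recovers generating probabilities
and effect structure, and the analysis is correctly calibrated under the
null. What they do not show: anything about real observers — real
response latencies, lapses, criterion drift, or learning are not modeled,
and the generating effect sizes are assumptions.

## Scoring

Attribution windows are half-open (onset, onset + 1 s]: a press exactly
at onset is *not* attributed (zero-latency responses are implausible),
a press exactly at onset + 1 s is. The first press in a window satisfies
the event; later presses in the same window are kept as unattributed.
Events are pooled across each condition's trials before rates are formed
(a full session considers 64 potential hits and 64 potential false alarms
per condition). Raw rates are reported uncorrected; d′ and ln β use the
(k + 0.5)/(n + 1) correction only. ln β uses the equal-variance Gaussian
closed form (z(FAR)² − z(HR)²)/2, positive = conservative. The optional
performance exclusion removes subjects whose *mean d′ across the three
conditions* falls strictly below 0.7 (the pooling rule is unstated in the
reference; the mean is the implementation's choice).

## Group statistics

`mixed_anova` implements the classical split-plot sums-of-squares
decomposition directly (between-group effect against subjects-within-
groups; condition and interaction against the within-subject residual),
including the intercept test of the grand mean against the between-
subjects error — the test that carries "observers are conservative" for
ln β. It requires complete data (no imputation) and at least two subjects
per group, and agrees with an independent projection-based decomposition
and with `pingouin.mixed_anova` to ~1e-9 on random balanced tables. No
sphericity correction is applied by default (the reference reports
uncorrected df); Greenhouse–Geisser is available via `gg_correction=True`.
Post hoc contrasts are two-sided paired t tests pooled across both task
groups (the reference reports a single p per pair and no interaction,
which is consistent with pooling), judged at α = 0.05/3 ≈ 0.017; they are
computed only for measures whose coherence effect is significant.
Within-subject normalization subtracts each subject's overall mean
(subtraction, not division, per the "relative to" phrasing).

## Problem sizes

Default test and reproduction runs use reduced problem sizes chosen to
keep estimates well inside their tolerance: 200 simulated sessions for
per-condition event totals (SE ≈ 0.33 events on an expectation of 64),
10,000 draws for count means, 1,000 counts-level cohorts for type-I
calibration (MC SE ≈ 0.7 points on 5%), and 1–2 kHz envelopes for
scheduling-only simulations as described above. All sizes are arguments,
and full-scale runs need no code changes.

## Known limitations

* No real-time presentation, screen rendering, audio playback, or SPL
  calibration; WAV and CSV/JSON artifacts are the outputs.
* The observer simulator has no decision-process dynamics (no
  accumulators, no cross-modal binding mechanism) — by design.
* The adaptive pre-test that produced the 12.25% average timbre
  perturbation is not modeled; the fraction is a parameter.
* Impulse-train spectral tilt and formant bandwidths are synthesis
  choices (config-exposed), not values from the reference design.
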