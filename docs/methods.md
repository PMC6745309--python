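# Methods

This note documents the analysis model, the synthetic-data model behind
the validation experiments, the numerical choices, and what the tests do
and do not establish about real recordings.

## The evoked-response model and its features

A TMS pulse over left M1 evokes the canonical TEP component sequence
N45, P60, N100, P180 (sign, nominal latency in ms). The pipeline treats
the trial-averaged evoked response per channel as the measurement and
extracts:

**Peaks.** Each component is searched in a half-open latency window —
N45 [30, 57), P60 [50, 80), N100 [80, 140), P180 [140, 250) ms
(literature-conventional windows around the nominal latencies). The
reported peak is the local extremum of largest magnitude in the window,
at sample resolution and with no smoothing. A `found` flag marks whether
that extremum has the component's canonical sign *and* exceeds 3× the
pre-stimulus RMS (t ≤ −50 ms). Magnitude outranks sign deliberately:
under the inhibitory protocol the late components can invert (the
"phase shift" that separates pathological from healthy responses), and
the inverted peak must be reported — flagged, not displaced by whatever
small noise wiggle happens to carry the expected sign. On noiseless
sign-canonical input the rule coincides with a windowed sign-constrained
argmax.

**Slopes.** Early slope = (A_N100 − A_P60)/(t_N100 − t_P60); late slope
= (A_P180 − A_N100)/(t_P180 − t_N100); slope ratio = late/early. Pure
finite differences of the detected peak coordinates. Slopes are computed
from the reported peak values even when flagged not-found (a strict mode
exists), because the sign reversal of the late slope under the
inhibitory protocol is precisely the feature of interest and would
otherwise be undefined.

**Charge transfer.** Q = ∫|V(t)|dt over 15–300 ms: the response lasts up
to ~300 ms, and 15 ms excludes the artifact-interpolated segment.
Rectified (unsigned) area is used so that biphasic responses do not
self-cancel. The integral is that of the rectified *linear interpolant*
of the samples — equal to the trapezoid rule away from zero crossings
and exact across them — which makes Q additive over window partitions
and agreeing with adaptive quadrature to ~1e-10 relative. Window edges
are inclusive (the trapezoid needs both); all *selection* windows in the
package are half-open [start, end).

**Input/output curve.** Per distinct single-pulse intensity the evoked
is averaged and the feature (Q by default, peak-to-peak optional)
extracted; the Boltzmann sigmoid floor + span/(1 + exp(−(I − I50)/k)) is
fitted by bounded least squares from a fixed 5 × 3 initialization grid
(I50 across the intensity range × k ∈ {2, 5, 10} %MSO), best SSE wins —
deterministic, no random restarts. With fewer than 4 intensity levels
the raw grid is returned unfitted, flagged.

**Connectivity.** Pearson r between channel evoked waveforms restricted
to 15–300 ms, computed on the subject-level average (not single trials).
Region aggregation averages r over all cross-electrode pairs; the
diagonal holds the mean within-group off-diagonal r. Group averaging
goes through Fisher's z (plain averaging of r is biased toward zero).
Undefined correlations (zero-variance channel) propagate as missing,
never imputed. Contrasts use pooled two-sample t-tests on Fisher-z
subject values; no multiplicity correction by default (matching the
statistical conventions of the source domain), Benjamini–Hochberg by
flag.

**Short-term plasticity.** Trials are classed by train frequency:
baseline ≤ 0.5 Hz, inhibitory 1–5 Hz, excitatory ≥ 20 Hz (boundaries
config-exposed; 0.5 Hz itself is baseline). STP features are
protocol/baseline ratios — STP-Q, late-slope STP, and their quotient —
so 1 means no modulation and a negative late-slope STP records a sign
inversion. The single-pulse pool is the reference. Region values
aggregate per-channel features by the group mean (mean of features, not
feature of the mean waveform).

**Classifier (demonstration rule).** A profile is `abnormal` iff the
median over region-roles of sign(late-slope STP) is positive, with at
least 4 regions defined. This is a minimal formalization of the observed
binary-step separation — healthy responses invert the late slope under
the inhibitory protocol, the mild-dementia phenotype does not — and is
explicitly not a clinical instrument.

## Preprocessing

1. **Pulse artifact**: samples in (−2, +10) ms around each pulse are
   replaced by a cubic polynomial through two flanking samples on each
   side — the simplest scheme that reproduces flat and linear trends
   exactly and cannot ring. Overlapping windows merge with a warning.
2. **Filtering**: zero-phase Butterworth band-pass 1–80 Hz (order 4,
   forward-backward), 50 Hz notch (Q = 30), polyphase resampling to
   1 kHz. Defaults preserve N45 morphology; all config-exposed.
3. **Epoching**: [−500, +500) ms per pulse, per-trial per-channel
   baseline mean over [−300, −50) ms subtracted (the baseline ends well
   before any pre-pulse leakage). Events that do not fit the recording
   are dropped and logged.
4. **Rejection**: a trial is dropped when any sample outside the
   artifact window exceeds 150 µV absolute, or a channel is flat
   (< 0.1 µV peak-to-peak). A hard error is raised if nothing survives;
   profiles require ≥ 50% retention.

## The synthetic cohort generator

The generator emulates the study protocol so the pipeline can be
validated against injected ground truth: 420 pulses per session — 160
single pulses (8 intensities 25–60% × 20), 100 inhibitory-train pulses
at 1 Hz, 160 excitatory-train pulses at 20 Hz — at 5 kHz by default
(validation experiments run at 1 kHz).

- **Waveform**: sum of four Gaussians at (45, 60, 100, 180) ms, widths
  (8, 8, 15, 25) ms, full-recruitment amplitudes (−3, +4, −8, +5) µV —
  amplitudes chosen to make windowed extrema analytically checkable.
- **Recruitment**: all amplitudes scale with 1/(1+exp(−(I−I50)/k)),
  default I50 ≈ 40% MSO, k = 5% MSO.
- **Spatial spread**: per-electrode gain (1.0 at C3 falling to 0.6
  occipitally) and lag (0–5 ms); contralateral homologs are attenuated
  ×0.7.
- **Interhemispheric coherence c**: a contralateral electrode receives
  c × its homolog's waveform + (1−c) × a latency-perturbed variant
  (component shifts +20, +30, −35, +45 ms; correlation with the original
  ≈ 0). c = 1 therefore gives homologous r = 1 exactly; no conduction
  lag is modelled on the coherent pathway — a deliberate simplification
  that makes c map directly onto the measured homologous correlation.
- **Protocol modulation**: inhibitory trains scale the waveform by m_q
  and multiply the segment after the P60→N100 zero crossing by
  m_slope/m_q. With the default |m_slope| = m_q this is a pure sign flip
  at a zero of the waveform, so |V(t)| is pointwise preserved: the
  injected STP-Q is exactly m_q and the injected late-slope STP exactly
  m_slope (up to a sub-sample interpolation effect < 0.5%). Excitatory
  trains scale by 1/m_q.
- **Noise**: per channel, 60% of variance 1/f (spectrally shaped), 30%
  white, 10% 50 Hz line, total single-trial RMS 1.6 µV by default
  (single-trial SNR ≈ 5 against the 8 µV N100). Pulses add a
  4000 µV decaying-exponential artifact (τ = 1.2 ms, ~5 ms long) —
  removed entirely by the interpolation step. Trial amplitudes jitter
  log-normally (σ = 0.08).
- **Phenotypes** (young / adult / elderly / md): amplitude scale 1.0 /
  0.9 / 0.8 / 0.7; coherence 0.85 / 0.70 / 0.55 / 0.35; P180 drift 1.0 /
  0.85 / 0.70 / 0.55; m_q 0.70 / 0.75 / 0.85 / 0.90 with m_slope = −m_q
  for healthy groups and +m_q for md (the reversal). These magnitudes
  are calibration constants encoding only the *direction* of the group
  effects (coherence and amplitude decline with age; charge-transfer STP
  rises; late-slope STP falls; mild dementia reverses its sign); they
  are not measured values. Cohort sampling jitters them per subject
  (log-normal σ 0.05/0.03 on scales, ±0.03 on coherence, ±1% on I50).
- **Timing**: single pulses at ~1.1 s spacing (labelled 0.1 Hz class —
  the class metadata, not the realized ISI, drives analysis); 1 Hz
  inhibitory trains keep neighbouring responses out of the 15–300 ms
  window; 20 Hz excitatory trains genuinely overlap, as they do
  physically.
- **Sham**: identical schedule and noise stream for the same seed,
  evoked amplitudes ×0.03, sham flag on every event.

What the generator does **not** emulate: volume-conduction forward
models, damped-sinusoid component shapes, ocular/muscle artifacts,
electrode drift, recharge artifacts, or realistic train-overlap
dynamics at 20 Hz. Passing the validation suite therefore shows the
*pipeline* is correct and well-calibrated on data with the stated
structure; it does not certify performance on human recordings.

## Validation experiments (scripts/acceptance.py)

Each quantity is recomputed from scratch under the seed passed on the
command line: charge-transfer agreement with adaptive quadrature (20
random composites); peak latencies vs dense-grid argmax (20 composites);
N100 recovery at SNR 5 with 40-trial averages (200 channels, band-limited
1–80 Hz as the pipeline leaves data); STP-Q recovery of injected
m = 0.75 (noiseless and SNR 5, 100 runs); Spearman monotonicity of
interhemispheric r across 5 coherence levels (20 replicates, 3 subjects
each); the sign-rule classifier on 10 healthy-elderly vs 10 md subjects
(noiseless and default noise); test-retest reliability with 9:1
true:noise variance, n = 30, against the attenuation closed form
E[r] = σ²_true/(σ²_true + σ²_noise) = 0.9 (200 runs); statistical closed
forms and the null type-I rate (2000 replications, 3 × 15 samples); and
the end-to-end 4-group × 5-subject cohort (420-pulse sessions simulated
at 1 kHz, written as BrainVision, analyzed to the full group report).
Problem sizes were chosen so the full script completes in a few minutes
on one CPU.

## Numerical and design choices

- Time convention: ms, pulse at 0; selection windows half-open,
  integration windows edge-inclusive.
- BrainVision output is int16 at 0.5 µV/bit (spanning ±16.384 mV);
  round-trip error is bounded by half a bit. Marker descriptions encode
  `S<intensity>/<frequency>/b<block>`; sham pulses use marker type
  `Sham`.
- The temporal ipsilateral group is {CP5, CP3, FC5}; the label "CF5"
  sometimes seen for this grouping is not a 10-10 electrode name and is
  interpreted as FC5, mirroring contralateral FC6.
- Slope-ratio direction is fixed as late/early; STP quotient as
  STP-Q / STP-slope.
- Fisher-z averaging keeps ±1 entries finite through the tanh
  back-transform; the diagonal is set to 1 where defined.
- Degenerate inputs: zero-variance channels yield missing correlations;
  zero baseline Q or late slope yields missing STP with flags; identical
  constant groups give t = 0, p = 1 by convention.
- Reliability is Pearson r as stated (it ignores systematic session
  shifts; an ICC variant would capture those but is out of scope).
- Unknown configuration keys are rejected; the effective config and its
  hash are echoed into every output directory, and profiles carry the
  hash in their provenance.

## Known limitations

- The classifier is a demonstration rule with no trained threshold,
  uncertainty, or validation on human data.
- Evoked connectivity is zero-lag waveform correlation; no spectral
  coherence, phase-locking or directed measures.
- Excitatory-train (20 Hz) features are contaminated by overlapping
  responses, as in real recordings; only the inhibitory protocol is used
  for STP validation.
- EDF input is read-only and expects the same marker conventions in its
  annotations.
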