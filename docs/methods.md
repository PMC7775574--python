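# Methods

This note records the models, defaults and numerical choices behind
`nfasym`, and what the synthetic tests do and do not demonstrate about
real recordings.

## Signal model and preprocessing

All computations operate on HbO concentration-change series (μmol/L)
sampled at 2 Hz from 8 channels, four per hemisphere over the dorsolateral
prefrontal cortex. The asymmetry signal is the difference of the
hemisphere means, `A = mean(L1..L4) − mean(R1..R4)`; with iid per-channel
noise of SD σ the asymmetry noise SD is σ/√2.

**FIR low-pass.** A linear-phase windowed-sinc (Hamming) kernel with
order 20 (21 taps) and 0.1 Hz cut-off, normalized to unity DC gain so means
are preserved exactly. Filtering is zero-lag: the input is edge-padded by
one kernel length and the group delay of order/2 samples is compensated by
center-aligned convolution, so a constant passes through unchanged and a
ramp is not laterally shifted. Measured stop-band attenuation at 0.9 Hz is
about −68 dB.

**Rest-epoch baselining.** fNIRS HbO values are relative measures; each
block's channel data are referenced to their mean over that block's Rest
epoch. This is shift-invariant for the reference-vs-NF comparison and the
dynamic mapping bounds, but it is what makes the one-sample
test-against-zero of the reference-free protocol meaningful.

**SMAR (sliding-window motion-artifact rejection).** A window of
`window_s = 5 s` slides one sample at a time; all samples of any window
whose peak-to-peak excursion exceeds `threshold_k = 5` times a robust scale
are flagged invalid. The scale is the median of the window-local SDs,
floored at the global SD of the series. The floor is a deliberate design
choice: it guarantees that a series whose overall excursion is
proportionate to its own variability (global peak-to-peak < k × global SD)
is never flagged, at the cost of reduced sensitivity when many artifacts
inflate the global SD — with sparse transients (≲ 2/min) detection is
essentially certain, and a lone 10-SD transient is always caught. Artifact
detection runs on the *raw* series, because the 0.1 Hz low-pass smears
short movement transients below detectability. Flagged samples are carried
as validity flags and dropped from all downstream statistics, never
interpolated, so reported sample counts are honest. An epoch keeping fewer
than `min_valid_fraction = 0.5` of its samples is unscorable.

**Detrending** (used by the RAP preset) subtracts the least-squares line
fitted over valid samples; it is applied to the asymmetry series after
filtering and before bound computation and scoring, and is not written
into the stored epochs, which always satisfy `asymmetry = left − right` of
the stored channel data.

## Feedback mapping

Dynamic bounds per block: `Min = mean + 1.28·SD` (sample SD, ddof = 1) of
the valid View-epoch asymmetry, `Max = Min + (max − min)` of the same
samples. 1.28 is the standard-normal 90th-percentile point, so for
normally distributed reference asymmetry ~90% of spontaneous variation
yields no feedback; a Monte-Carlo check at n = 10⁶ reproduces 90.0%. The
sample-SD convention matches the t/Cohen's-d machinery. A constant
reference epoch (zero range) is rejected as degenerate. The reference-free
preset uses fixed bounds (0, 1.1). Feedback is
`clip((A − Min)/(Max − Min), 0, 1)` per 2 Hz sample; values outside the
band clamp to 0/1 (no feedback below threshold, saturation above).

## Success statistics

Scored epochs are trimmed of their first `delay_trim_s = 7 s`
(hemodynamic latency); a 22 s epoch at 2 Hz keeps 30 of 44 samples on the
half-open sample grid. The parametric test is a pooled-variance
independent-samples t-test of NF vs reference asymmetry; the critical value
is *fixed* at 2.05 (two-tailed α = 0.05 at df = 28) regardless of the
actual per-block n, reproducing the behavior of the original real-time
software, and applied one-sidedly (success ⇔ t > 2.05). With 30 + 30
samples the statistic really has 58 df, so the realized one-sided type-I
rate is ≈ 2.2–2.4% rather than 2.5% — the simulation suite checks it stays
within [1.5%, 4%]. Protocols without a reference epoch use a one-sample
test against zero asymmetry (configurable baseline); this is the resolution
of an ambiguity in the sources, which describe the test only as
"real-time" with threshold 0. The bootstrap variant resamples each epoch
with replacement (default B = 2000) and declares success when the central
95% percentile interval of `mean(NF*) − mean(View*)` lies above zero; on
clearly separated or clearly null blocks it agrees with the parametric
verdict ≥ 95% of the time.

Effect sizes: Cohen's `d` with pooled SD, and `r = sqrt(t²/(t² + df))`
with the fixed df = 28 — `r` is named but not defined in the sources, so
this standard t-to-r conversion is a recorded design choice.

Experiment summaries exclude practice blocks; the subject success rate is
the fraction of subjects succeeding on at least half of their scored
blocks (⌈n/2⌉).

## Protocol presets

| | ANG | RAP | HEU |
|---|---|---|---|
| scored blocks / practice | 6 / 2 | 8 / 1 | 6 / 3 |
| epoch plan (s) | Rest 30, View 22, NF 22 | Rest 30, View 40, NF 40 | Rest 30, NF 30 |
| mapping | dynamic | dynamic | fixed (0, 1.1) |
| filtering / SMAR / detrend | – | FIR + SMAR + detrend | – |
| success test | parametric | bootstrap | parametric (vs 0) |
| success measure | d | r | r |

Epoch lengths are reported inconsistently across the sources (scheduled vs
effective durations); the presets use the scheduled durations above — ANG's
22 s epochs leave exactly 15 s = 30 samples after the 7 s trim — and every
duration is configurable rather than hard-coded. The Rest duration is
never stated; 30 s is a conventional choice. The dynamic bounds are
computed once per block, after the View epoch ends and before NF begins;
the few seconds of scheduling latency mentioned in the sources are treated
as latency, not as a data-selection rule.

## Dataset format

One JSON document per experiment: generic header (sampling rate, channel
count, normalized FIR kernel, experiment id), a marker table, and subjects
with a (channel × time × block) tensor, a (time × block) asymmetry matrix,
normalized time and marker vectors, and per-block records holding
whole-block / View / NF epoch slices, mapping bounds (absent for
fixed-mapping blocks), the [0, 1] feedback series and the success flag.
Arrays are stored as nested lists with explicit shape metadata and floats
in full repr, so save → load → save is byte-identical under canonical key
ordering. Marker semantics are per-file: only "NF epoch" (id 54) is a
required entry; the shipped writer also uses 50 (Rest), 52 (View) and 0
(inter-epoch), but readers must resolve ids through the table. Validation
reports every violation with its JSON path instead of stopping at the
first; saving refuses invalid datasets.

## Synthetic generator

Each channel is baseline (per-block offset, SD 0.2 μmol/L) + shared linear
drift (slope SD 0.002 μmol/L/s) + iid Gaussian noise (SD 0.3 μmol/L).
During NF, responders receive `+δ/2` on left channels and `−δ/2` on right
channels, where `δ = effect_size × (noise_sd/√2)`, ramped by a gamma-CDF
hemodynamic response (shape 4, scale tuned so the CDF reaches 0.95 exactly
at the 7 s delay). The symmetric injection keeps channel sums stable and
isolates the asymmetry pathway, and makes `effect_size` directly
comparable to the Cohen's d recovered after the delay trim. Motion
artifacts are Poisson-distributed (~1.5 s decaying transients, amplitude
10 × noise SD, simultaneous on all channels), off by default. Responder
status is drawn once per subject with probability
`responder_fraction = 0.7`, reflecting the substantial non-responder
("BCI illiteracy") fraction reported in NF studies; `effect_size = 1.5`
makes responder blocks succeed nearly always, so experiment-level success
rates land near the responder fraction, with binomial variation across
seeds at n = 11 subjects.

What the generator does *not* emulate: autocorrelated physiological noise
(cardiac, respiratory, Mayer waves), channel-specific optode-coupling
drift, habituation or learning across blocks, and realistic artifact
morphology. Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic and its statistical calibration under the stated
noise model — not performance on real recordings, where serial correlation
inflates the effective type-I rate of sample-level t-tests.

## Problem sizes and determinism

Simulation-based checks use 10,000 null blocks, 1,000 power blocks, 200
recovery blocks and 10⁶ reference samples; a full synthetic experiment is
11 subjects × 9 blocks. All randomness flows through
`numpy.random.default_rng` seeded explicitly; dataset generation is
byte-deterministic given its seed, and the acceptance script derives all
sub-seeds from its `--seed` argument via `SeedSequence`.

## Known limitations

- The fixed df = 28 criterion is deliberately faithful to the original
  software rather than statistically optimal; per-block df would be
  slightly more powerful and is not provided.
- SMAR sensitivity degrades when artifacts are dense enough to inflate the
  global SD floor (see above).
- The stored-epoch schema cannot carry validity flags or detrended views,
  so a re-scoring of a file reproduces the parametric/bootstrap tests on
  the stored asymmetry but re-derives SMAR masks only from the raw
  channels.
- Bootstrap success depends on the resampling seed near the decision
  boundary; summaries therefore accept a seed and report it.
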