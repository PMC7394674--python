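# Methods

## Scope and signal chain

`abpsim` models the unidirectional chain

```
scripted vitals (1 Hz) → beat synthesis (250 Hz) → 0–5 V mapping → 12-bit DAC codes
                                                        ↓
                               pulse-contour analyzer (verification)
```

The monitor side is represented only by the analyzer's openly defined beat
statistics (SBP, DBP, PP, MAP, HR, PPV). Proprietary pulse-contour
algorithms that estimate flow quantities (cardiac output, stroke volume,
systemic vascular resistance, SVV) are deliberately not modeled: their
internals are not public, and imitating them would suggest a fidelity the
package cannot have.

## Vitals scenarios

A scenario is a script: ordered segments `(t, HR, SBP, DBP)` with a total
duration, interpreted either as a step function (`hold`, default: a
segment takes effect at exactly its start time, half-open intervals) or
with component-wise linear interpolation (`linear-ramp`). Scripts stand in
for the live once-per-second feed of a physical patient simulator; there
is no closed-loop physiology (no baroreflex, no respiratory modulation).

Validation clamps HR into **[0, 350] bpm** — the transmissible range of
the simulator's digital HR channel — and pressures into **[0, 500] mmHg**.
The simulator interface declares no pressure limits of its own, so the
package adopts the span representable on the analog output: anything above
500 mmHg cannot be encoded in 0–5 V anyway. Clamps warn but never raise;
SBP ≤ DBP with a nonzero HR raises, because no arterial pulse can be
synthesized from it. `HR = 0` is legal and means "no beats": the engine
emits a flatline at the current DBP (the decay target of an unperfused
arterial tree — any constant would be defensible; this one is continuous
with the preceding diastole) and logs a warning.

### Synthetic presets

The generator emulates the three scenario families a simulation center
would script, at textbook adult values:

| preset            | profile                                              |
|-------------------|------------------------------------------------------|
| `steady`          | constant 70 bpm, 120/80 mmHg                         |
| `hemorrhage-ramp` | HR 70→130 bpm, SBP 120→60, DBP 80→40 over the run (5 s steps) |
| `hypotension-step`| 70 bpm 120/80 → 90 bpm 80/50 at mid-run              |

Noise is additive Gaussian per vital per segment (one segment per second
when noisy), seeded and reproducible. Raw noisy values may leave the
transmissible ranges — they are clamped at sampling time, which is exactly
how the package exercises its out-of-range handling — but DBP is kept at
least 5 mmHg below the clamped SBP so generated scenarios never trip the
SBP ≤ DBP error. What the generator does **not** emulate: beat-to-beat
variability, arrhythmia, respiratory PP modulation, measurement artifacts.
Passing round-trip tests therefore show the chain is faithful to its
commands, not that the waveform is physiologically complete; in
particular PPV of any constant-vitals run is exactly 0.

## Pulse template

A template is one beat, min-max normalized: `n_i = (x_i − min) / (max −
min)`, so min = 0 and max = 1 *exactly* (this is what makes the later
SBP/DBP scaling exact). Endpoints must be ≤ 0.05 so that concatenated
beats join continuously; the stream-continuity property (junction jumps ≤
5 % of pulse pressure) follows directly. Templates shorter than 8 samples
are rejected as degenerate.

Real single-beat recordings cannot be shipped, so the default template is
parametric: a half-cosine systolic upstroke peaking at half the systolic
fraction of the cycle, an exponential decay tuned to reach ~2 % of pulse
height by cycle end, and a Gaussian dicrotic wave (amplitude 0.15,
σ = 0.05 cycle) shortly after end-systole. Defaults: systolic fraction
0.3, reference metadata 250 Hz / 47 bpm — the sampling rate and heart
rate of the resting recording the interface was designed around, giving
`round(250·60/47) = 319` samples. An optional seed jitters decay constant
and dicrotic timing by a few percent to emulate inter-subject morphology
variation; the construction is deterministic for a fixed seed. The
morphology is fixed per run: varying amplitude and rate but not wave
shape is an inherent limitation of template replay.

## Waveform engine

Per beat: interpolate the template onto `round(f_out · 60 / HR)` uniform
phase points (treating the beat as one period of a cyclic signal), re-pin
to [0, 1] exactly, then scale `p_i = n_i·SBP + (1 − n_i)·DBP` (written in
this form so both extrema are floating-point exact). Rounding of beat
lengths is half-away-from-zero, stated so sample counts are reproducible:
at 250 Hz, 60 bpm → 250 samples, 350 bpm → 43 samples. Sample timestamps
are `k / f_out` from an integer counter, so spacing is exact and no float
drift accumulates. A constant-HR run of duration `T` yields
`round(HR·T/60) ± 1` beats (the last beat is emitted whole if it starts
before `T`, so a stream may overrun the nominal duration by less than one
beat).

The three-role streaming contract — coordinator feeding a bounded ring
buffer with the template cycle, a 1 Hz vitals producer, a waveform
consumer — runs in two modes with identical output: `deterministic`
(single thread, virtual clock; the test surface) and `threaded` (real
threads synchronized on the same virtual clock: the consumer blocks until
the poll covering a beat's start time has been published). Wall-clock
pacing is available for live demonstration but adds nothing to the
semantics, and timing jitter of a paced run is hardware-dependent, so it
is only smoke-tested. Buffer capacity defaults to four template beats;
the `block` policy is lossless, `overwrite` drops oldest samples (counted)
to emulate real-time dropout.

Update policies: `beat-atomic` (default) applies new vitals at the next
beat boundary — no beat is synthesized from two commands, avoiding
mid-beat discontinuities. `immediate` rescales the remainder of a beat as
soon as a new poll lands; beat length (HR) remains fixed at beat start,
since re-timing a beat mid-flight has no well-defined phase.

## Analog output

The mapping is the monitor's input convention: 0 mmHg ↔ 0 V, 500 mmHg ↔
5 V, linear between. The quantizer uses `code = round(v · (2¹² − 1) / 5)`,
half-away-from-zero — i.e. full scale is code 4095. Hardware DACs of this
class divide by 4096 instead; the difference is sub-LSB and the package
fixes and tests one convention rather than guessing the bench wiring. The
worst round-trip pressure error is half an LSB, `0.5 · 500/4095 ≈
0.061 mmHg`. The output stage clamps rather than raises on out-of-range
pressures: it must never crash a running stream. Waveform files are CSV
(`t_s,p_mmhg,volts,dac_code`) with floats at 6 significant digits, chosen
so write → read round-trips are stable at stated precision. The DAC
itself is a pluggable driver interface with a recording mock; requesting
hardware output with no driver raises explicitly, never silently.

## Contour analyzer

Beats are segmented at diastolic troughs: local minima of the pressure
series at least `60/350 s` apart (one beat at the transmissible HR
ceiling) with prominence ≥ 25 % of the signal range; series endpoints
count as boundaries when they sit in the bottom 15 % of their local
half-second window, so a stream that starts and ends at diastole yields
beats + 1 boundaries. Beat windows are half-open `[trough_i, trough_{i+1})`
— the closing trough is the next beat's first sample, which keeps a
pre-transition beat's DBP uncontaminated by the next command. A flatline
has zero beats.

MAP uses the clinical approximation DBP + PP/3 rather than the time
integral (determinate, textbook, independent of morphology). PPV is
`100·(PPmax − PPmin)/mean(PPmax, PPmin)` over a trailing window, default
10 s — a typical monitor averaging window. HR is 60 / mean beat period
over the window.

Round-trip verification runs the deterministic pipeline, passes the
stream through the voltage/code quantization (as the monitor would see
it), and compares per-beat recoveries with each steady segment's
validated command, excluding one transition beat after each segment
change; a scenario with no steady segment retaining ≥ 5 beats is too
short to verify. Expected fidelity at 250 Hz: pressures within half an
LSB (≪ 0.5 mmHg), HR within the period-rounding error (≪ 2 bpm).

## Problem sizes

Defaults are desk-scale by design: round-trip checks use 20–60 s runs at
250 Hz (5,000–15,000 samples); the randomized voltage-range and
thread-equivalence properties use 1,000 × 4 s and 20 × 6 s runs
respectively; the acceptance script runs 1,000 × 10 s scenarios. All
complete in seconds on one core.

## Known limitations

- Fixed beat morphology; no pathology-specific waveforms, arrhythmia or
  valve disease.
- No respiratory modulation, so PPV/SVV physiology cannot be exercised;
  PPV of synthesized streams is identically 0.
- No flow-side estimates (CO/SV/SVR/SVV) — out of scope by design.
- The beat detector assumes clean template-derived signals; it is not an
  arrhythmia-tolerant clinical detector.
- Wall-clock pacing accuracy and I²C bus behavior of real hardware are
  not modeled.
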