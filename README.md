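# abpsim — scripted arterial blood-pressure waveform simulation

Minimally invasive hemodynamic monitors (LiDCO-class pulse-contour
devices) read a patient's arterial pressure as an analog voltage and
derive flow-side parameters from the waveform shape. Patient simulators
used in anesthesia training publish only scalar vitals — heart rate (HR),
systolic (SBP) and diastolic (DBP) pressure, once per second — so such
monitors cannot normally be connected to them. `abpsim` closes that gap in
software: it replays a normalized single-beat arterial template at the
scripted vitals, producing a continuous pressure waveform and its analog
representation (0–5 V, one volt per 100 mmHg, 12-bit DAC codes) that a
monitor-side consumer can interpret as if it came from a real arterial
line. A built-in pulse-contour analyzer closes the loop at the desk: it
re-detects beats and verifies that the commanded vitals are recovered.

It is aimed at simulation-center engineers and researchers in
simulation-based medical education who need a reproducible, hardware-free
stand-in for the simulator → monitor signal chain.

## The model

Let `n(φ)`, `φ ∈ [0, 1)`, be a single arterial beat min-max normalized to
`[0, 1]` (recorded, or the packaged parametric beat: systolic upstroke,
exponential diastolic decay, dicrotic wave; reference metadata 250 Hz,
47 bpm). For commanded vitals (HR, SBP, DBP) each beat is

* **resampled** onto `round(f_out · 60 / HR)` uniform phase points
  (`f_out` = 250 Hz by default), re-pinned to min 0 / max 1;
* **rescaled** affinely, `p_i = n_i · SBP + (1 − n_i) · DBP`, so the beat
  maximum is exactly SBP and the minimum exactly DBP;
* **mapped** to volts, `v = clamp(p, 0, 500) · 5/500`, and quantized to
  `code = round(v · 4095 / 5)`.

Vitals are polled at 1 Hz; under the default beat-atomic policy a change
takes effect at the next beat boundary. The producer, template ring
buffer, and waveform consumer run either single-threaded on a virtual
clock (bit-reproducible) or as real threads with identical output. The
analyzer segments beats at diastolic troughs (refractory 60/350 s),
extracts per-beat SBP/DBP, pulse pressure PP = SBP − DBP, MAP ≈ DBP +
PP/3, windowed HR and pulse pressure variation
PPV = 100·(PPmax − PPmin)/mean(PPmax, PPmin). It is *not* a PulseCO
re-implementation; cardiac output, stroke volume, SVR and SVV are out of
scope.

## Worked example

```python
from abpsim import Scenario, VitalsSample, run_roundtrip, max_abs_errors

scenario = Scenario((VitalsSample(0.0, 70.0, 120.0, 80.0),), duration=60.0)
report, engine = run_roundtrip(scenario)   # synthesize → quantize → analyze
print(report.to_string(index=False))
```

prints

```
 segment_t metric  commanded  recovered  abs_error
       0.0    sbp      120.0 120.024420   0.024420
       0.0    dbp       80.0  79.975580   0.024420
       0.0     hr       70.0  70.098071   0.098071
```

The 60 s run emits 71 beats (15,194 samples at 250 Hz) spanning
80–120 mmHg → 0.800–1.200 V → DAC codes 655–983. The analyzer recovers
the commanded 120/80 mmHg within 0.025 mmHg — the pressure granularity of
one half DAC step, 0.5·500/4095 ≈ 0.061 mmHg, bounds this error — and the
commanded 70 bpm within 0.1 bpm (beat lengths are whole samples, so HR is
recovered to the nearest representable period).

The same chain is available from a shell:

```sh
abpsim make-scenario --kind hemorrhage-ramp --duration 60 --out scenario.csv
abpsim run --scenario scenario.csv --duration 60 --out waveform.csv
abpsim analyze --in waveform.csv --scenario scenario.csv --report report.csv
```

## Layout

| module            | provides                                             |
|-------------------|------------------------------------------------------|
| `abpsim.vitals`   | scenario files, 1 Hz sampling, range validation, presets |
| `abpsim.template` | pulse templates: normalization, synthesis, file I/O  |
| `abpsim.engine`   | beat resampling/scaling, ring buffer, streaming pipeline |
| `abpsim.output`   | mmHg↔V mapping, 12-bit quantizer, waveform files, DAC stub |
| `abpsim.contour`  | beat detection, per-beat features, PPV, round-trip report |

See `docs/methods.md` for the full methodological notes.
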