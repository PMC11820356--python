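# hrvb

Resonance-frequency (RF) breathing assessment and heart-rate-variability
biofeedback toolkit.

Slow paced breathing near a person's resonance frequency (~4.5–6.5
breaths/min) maximally amplifies heart-rate oscillations. This package
implements the computational core of a remote RF-biofeedback workflow:

- **`hrvb.signals`** — RR-interval series I/O (plain CSV), R-peak detection,
  artifact handling, and uniform instantaneous-heart-rate curves.
- **`hrvb.metrics`** — SDNN / RMSSD / pNN50, Welch LF/(LF+HF) spectral
  balance, per-breath peak-trough amplitudes, Hilbert phase-locking value,
  and pre/during/post training-effect reports.
- **`hrvb.rf`** — RF determination: the stepped-and-ranked method (rank
  every trialled frequency under three HRV metrics, intersect the top-3
  sets, break ties by amplitude), a time-domain-only variant, the sliding
  sweep (one breath per frequency, 0.01 breaths/min resolution), and the
  hybrid strategy (stepped first, sliding fine-tuning within ±0.5
  breaths/min).
- **`hrvb.pacing`** — stepped/sliding/fixed pacer protocols (default
  8 → 4.5 breaths/min in 0.5 steps, 3 min each), phase-continuous pacer
  waveforms, the adaptive 0.25-breaths/min guidance rule, repeated-deviation
  alerts, and weekly adherence checks (≥4 sessions of ≥15 min).
- **`hrvb.simulate`** — a seeded cardiorespiratory simulator: respiratory
  sinus arrhythmia driven through a second-order resonator with
  subject-specific resonance, plus HF modulation, low-frequency wander,
  breathing-phase drift/jitter, and white interval noise. Ground truth
  travels with every session, enabling parameter-recovery testing.
- **`hrvb.stats`** — Bland–Altman agreement (1.96 × sample-SD limits),
  descriptive rows (population SD), and an exact paired Wilcoxon
  signed-rank test (full sign-assignment enumeration up to n = 25,
  tie-corrected normal approximation beyond).
- **`hrvb.datasets`** — small packaged reference tables (paired RF values
  from the two assessment methods, a recorded rank-table worked example).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
decision, agreement statistics, parameter-recovery rates, invariant
suites); the rest are unit and property tests per module.

## CLI

```bash
hrvb simulate --n 3 --seed 7 --protocol stepped-default --out-dir sim_out
hrvb assess --method stepped --rr sim_out/subj01_rr.csv \
    --protocol stepped.yml --out decision.txt
hrvb compare --out agreement.txt          # packaged paired-RF table
hrvb monitor --sessions sessions.csv --out monitor.txt
hrvb report --pre pre.csv --during during.csv --post post.csv --out rep.txt
```

Protocol configs are small YAML files, e.g.

```yaml
kind: stepped
grid_hi: 8.0
grid_lo: 4.5
step: 0.5
step_duration: 180
```

All outputs are deterministic for a fixed configuration and carry a header
with the tool version, a config hash, and the seed.

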