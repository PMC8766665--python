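# matrixstim

Software platform for **spatiotemporal "matrix" stimulation** of neural
circuits on multi-electrode arrays — pattern design and compilation, the
time-division-multiplexed digital→analog chain, a virtual cortical slice,
and the automated electrophysiology + calcium-imaging analysis that turns
patterned stimulation into maps, efficacies, and plasticity statistics.

It is aimed at slice electrophysiologists and systems neuroscientists who
want to design multi-site stimulation protocols (tetani, associative
pairings, moving bars, sequence scans), verify exactly what a
sample-and-hold multiplexed stimulator will deliver per electrode, and
exercise a full analysis pipeline — without hardware or tissue.

## What's inside

* **`patterns`** — a `StimulationMatrix` is an ordered list of
  (time, voltage, electrode) events.  Builders produce the standard
  protocols: voltage-mapping scans (2–4.5 V at 0.33 Hz), tetanic bursts
  (10 × 4 pulses at 100 Hz, 150 ms gaps), associative pairing
  (strong→weak, 15 ms offset, 100 reps at 0.2 Hz), moving bars (8 columns
  at 80 ms → 640 ms sweeps), row-major sequence scans (5 s spacing), and
  seeded unpatterned controls.  All pulses are charge-balanced biphasic
  square pulses, 0–4.5 V per direction.
* **`mux`** — compiles a matrix into a clocked stream of 6-bit-address /
  8-bit-voltage words (64 channels; one more address bit doubles
  capacity) and reconstructs per-channel sample-and-hold waveforms, with
  round-trip guarantees of one clock slot in time and half an LSB in
  amplitude.
* **`slice_sim`** — a seeded virtual slice: threshold-and-radius neuron
  activation (all-or-none, sub-millisecond latency jitter), heterogeneous
  synaptic inputs onto a patched cell (weak / strong / direct / silent),
  pharmacology switches (TTX, NBQX, AP5, bicuculline), three plasticity
  rules (tetanic, associative capture, sequence potentiation), and
  calcium movies with flicker, photobleaching, and trial-to-trial
  response variability.
* **`ephys`** — automated spike and EPSC detection (median + k·MAD
  thresholds, artifact blanking, accept flags), efficacy, activation and
  EPSC maps, latency jitter.
* **`imaging`** — ROI traces, flicker/bleach correction, stimulus-locked
  ΔF/F%, interpolated response maps, electrode-aligned population maps,
  and the paired-t-test **network assay**.
* **`matrixstim` CLI** — `build`, `encode`, `simulate`, `analyze-ephys`,
  `assay`, `demo`, `validate`.

See `docs/methods.md` for the models, parameters, and design decisions.

## Worked example

Associative capture of a weak synaptic input, end to end:

```python
from matrixstim import generate_slice
from matrixstim.pipeline import (
    associative_capture_experiment, latency_jitter_experiment, sequence_assay,
)
from matrixstim.slice_sim import copy_slice

slc = generate_slice(seed=1)          # 150 neurons on an 8x8, 200 um array

res = associative_capture_experiment(copy_slice(slc), seed=1)
print(res["strong_label"], res["weak_label"])
print(res["weak_efficacy_pre_pct"], res["weak_efficacy_post_pct"])
print(res["strong_efficacy_pre_pct"], res["strong_efficacy_post_pct"])

mean_ms, spread_ms, sd_ms = latency_jitter_experiment(copy_slice(slc), seed=1)
print(round(mean_ms, 2), round(spread_ms, 2))

assay = sequence_assay(copy_slice(slc), seed=1)   # 28 ROIs, 6 training sweeps
print(assay.n_rois, round(assay.mean_ratio, 2), assay.p_value)
```

prints

```
(5, 3) (6, 6)
0.0 100.0
100.0 100.0
3.06 0.9
28 1.3 0.00018262997483599672
```

Reading it: the experiment finds a superthreshold ("strong") input at
electrode row 5 / column 3 and a subthreshold ("weak") one at row 6 /
column 6.  Before pairing the weak input fires the patched cell on 0% of
test stimuli and the strong one on 100%; after 100 strong→weak pairings
at a 15 ms interval and 30 min of consolidation the weak input reaches
100% efficacy while the strong input is unchanged.  Evoked spikes across
50 identical pulses land within a 0.9 ms window (mean latency ≈ 3 ms).
Sequence training potentiates the 28-ROI network response (mean
after/before ratio 1.30, paired two-tailed t-test p ≈ 2 × 10⁻⁴); the same
training under NBQX + AP5, or with channel-shuffled "unpatterned"
stimulation, produces no significant change.

The same flow is scriptable from the shell:

```bash
matrixstim build pairing --strong-channel 34 --weak-channel 45 --out pairing.json
matrixstim encode pairing.json --out stream.csv      # (slot, address, code) words
matrixstim demo --seed 1 --outdir demo_out           # all three experiments + JSON summary
```

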