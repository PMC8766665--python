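# Methods

`matrixstim` is a software re-creation of a multi-electrode "matrix
stimulation" platform for brain slices: a pattern-design layer, the
digital→analog multiplexing chain, a virtual cortical slice that stands in
for the biological preparation, and the automated analysis used to read the
experiments out.  This note records the models, the parameters that matter,
and the design choices made where the underlying physiology or hardware
leaves them open.

## Stimulation patterns

A stimulation matrix is an ordered list of (time, voltage, electrode)
events on a planar array (default 8×8, 200 µm pitch).  Stimuli are
charge-balanced biphasic square pulses, positive phase first, 0–4.5 V per
direction, typically 1 ms per phase.  Onsets are stored as integer
microseconds so that sorting and codec slotting are exact; simultaneous
events are legal and tie-break by ascending channel.

Protocol builders encode the standard slice protocols:

| builder | defaults |
|---|---|
| `build_mapping_scan` | one pulse per (electrode, voltage), 2–4.5 V in 0.5 V steps, 0.33 Hz |
| `build_tetanus` | 10 bursts × 4 pulses at 100 Hz, 150 ms silent gap between bursts |
| `build_pairing` | strong→weak, 15 ms offset, 100 repetitions at 0.2 Hz |
| `build_moving_bar` | whole columns in synchrony, 80 ms steps (640 ms sweep over 8 columns), repeated every 10 s |
| `build_sequence_scan` | row-major site traversal, 5 s between stimuli; training = 6 sweeps without pause |
| `build_unpatterned_control` | same onsets and amplitudes, channels redrawn uniformly at random (seeded) |

Interpretive choices: "separated by 150 ms" for tetanic bursts is read as
the silent interval between burst offset and the next onset; the pairing
clock is pair-onset to pair-onset; the moving-bar sweep period includes
the trailing interval after the last column (8 × 80 ms = 640 ms).

## Multiplexing codec

The hardware chain — one DAC feeding demultiplexers and per-channel
sample-and-holds — is modeled as a clocked stream of (address,
voltage-code) words.  Defaults: 6 address bits (64 channels; each extra
bit doubles capacity), 8 voltage bits over ±4.5 V (bipolar mid-tread,
0 V → code 128 by round-half-up; the DAC coding is not dictated by the
hardware, so the mid-code is fixed by convention), and a 1 MHz slot clock
so a full 64-channel refresh cycle takes 64 µs.  Channels are updated
event-driven (only on waveform edges) rather than cyclically; under
zero-order hold the reconstruction is identical, and idle channels hold
their last value.  Guarantees: each edge lands in a slot within one slot
period of its ideal time (simultaneous edges serialize within a cycle in
ascending address, adding one slot each), and quantization error is at
most half an LSB (9/255/2 ≈ 0.018 V).

## Virtual slice

The simulator is phenomenological: it reproduces the measured
input–output contracts of the preparation, not membrane biophysics.

**Activation.** Each neuron has a position and a voltage threshold drawn
uniformly on [2, 4.5] V.  A stimulus of amplitude V on electrode e fires a
neuron iff V ≥ threshold and the neuron lies within the activation radius
r(V) = r_max·(V−V₀)^α / ((V−V₀)^α + k^α), with r_max = 400 µm, V₀ = 2 V,
k = 1 V, α = 2 (r(3 V) = 200 µm, r(4 V) = 320 µm).  This produces
all-or-none responses per site and concentric activation maps that grow
with intensity.  Spike latency is 3 ms plus truncated-Gaussian jitter
(σ = 0.2 ms, clipped at ±0.45 ms).  The truncation is deliberate: it
bounds the across-trial latency range at 0.9 ms, making the sub-millisecond
temporal-precision contract hold for any number of repeated trials rather
than only in expectation.  Refractory period 5 ms.

**Transmission.** A patched cell near the array center receives synapses
from other neurons with probability exp(−d/500 µm) and EPSC weights
10 pA + Exp(60 pA) (delays 2–6 ms).  Presynaptic spikes deposit EPSCs
(difference of exponentials, rise 1 ms, decay 8 ms); summed synchronous
drive ≥ 100 pA fires the patched cell.  At a fixed 3 V test voltage this
yields the observed heterogeneity of input sites: direct activation
(the patched cell itself within radius — rendered in voltage clamp as a
clipped escape transient), strong (superthreshold synaptic), weak
(subthreshold, ≥ 30 pA), or silent.  Generation parameters were chosen so
that a central patched cell offers at least one strong and one weak input
in ≥ 90% of seeds (verified by Monte-Carlo in the tests).

**Pharmacology.** TTX silences all spiking; NBQX removes AMPA EPSCs;
NBQX + AP5 blocks all plasticity induction; bicuculline removes a fixed
inhibitory damping factor (0.8) applied to calcium response amplitudes —
the only quantitative role inhibition plays here.

**Plasticity.** Three rules, all no-ops under NBQX + AP5 (or TTX), with
multipliers capped:

1. *Tetanic*: synapses recruited by the tetanized site gain ×1.5.
2. *Associative capture*: a stimulus earns a pairing credit when it falls
   within 15 ms after a patched-cell spike evoked by a different input.
   After induction, credited inputs' synaptic multipliers follow a
   saturating exponential of consolidation time,
   m(t) = 1 + (m_max−1)·f·(1−e^(−t/τ)), with m_max = 4, τ = 6 min and
   f = credits/100, so full pairing reaches its endpoint well within the
   30 min consolidation horizon and a ≥ 30 pA weak input crosses the
   100 pA spiking threshold — efficacy steps from 0% to 100%.  Only the
   endpoint and timescale are constrained by observation; the saturating
   form is the simplest dynamics consistent with both.
3. *Sequence potentiation*: a site earns one credit per training event
   that terminates a spatially contiguous chain of three events (both
   preceding steps within 1.5 electrode pitches and 10 s).  Per-site
   response gains grow by 0.08 per credit (cap 3×).  The three-event
   chain requirement is what separates ordered sweeps from the
   "unpatterned" control: a random channel sequence forms such chains
   with probability ≈ 0.008 per event, versus almost every event inside
   a row-major sweep or moving bar.  Moving-bar and row-major sequence
   training are deliberately handled by this single rule.

**Calcium imaging.** Each neuron has a Gaussian spatial footprint
(σ = 40 µm) on a movie (default 256×256 px, 10 Hz) covering the array
plus a 200 µm margin.  A spike adds a fast-rise (0.1 s), exponentially
decaying (1.5 s) transient of peak ΔF/F 0.5 at the neuron, scaled by the
site's plasticity gain, the inhibitory damping factor, and a per-spike
trial-to-trial amplitude factor (CV 0.15) — calcium responses in slices
are not stereotyped, and this variability is what gives the network
assay realistic, per-ROI-independent measurement noise.  The movie is
multiplied by per-frame lamp flicker (σ 2%) and a monotone photobleach
(τ = 600 s), plus white pixel noise.

## Analysis

**Spikes** are threshold crossings 30 mV above the trace median with a
2 ms lockout (DC-offset invariant).  **EPSCs**: stimulus windows are
blanked (2 ms bridge), the trace is low-pass filtered at 1 kHz
(zero-phase Butterworth), and onsets are marked where the finite
difference over the 1 ms rise timescale drops below median − 5·MAD;
amplitude is local baseline minus trough.  Events below
max(8 pA, 6× robust trace noise) are kept but flagged unaccepted — the
accept flag is the programmatic stand-in for post-hoc manual
verification.  Events whose rise falls inside a blanking window are
censored by construction.  **Efficacy** is the percentage of stimuli
followed by a spike within 50 ms.  Activation maps, the mean
spike-evoking distance per voltage, and EPSC amplitude maps (direct
sites flagged) are assembled per electrode.

**Imaging**: ROI traces (80 µm radius around each electrode) are divided
by the per-frame global median trace (flicker; the median resists bias
from the minority of responding ROIs), then by a per-ROI single
exponential fit on stimulus-free samples (bleach).  ΔF/F% per stimulus
uses a 0.5 s pre-stimulus baseline mean and a 1 s post-stimulus peak.
Response maps interpolate bilinearly on the electrode grid (the field
passes exactly through measured sites); population maps align maps on
the stimulated electrode before averaging.  The network assay compares
per-ROI responses before vs after training with a paired two-tailed
t-test (identical inputs are reported as p = 1 rather than NaN).

## What the generator does and does not emulate

The virtual slice makes every analysis stage testable against ground
truth: detection against injected event times and amplitudes, maps
against generating thresholds/weights, the assay against known gains,
and the paired test against a true null (rejection rate ≈ nominal at
α = 0.05 over 200 seeded runs).  It does **not** model conductances,
axonal (antidromic) activation beyond the radius law, short-term
dynamics, spontaneous activity, inhibitory circuitry (beyond the damping
factor), motion, or optical sectioning — so green tests certify the
pipeline's correctness on data obeying the stated contracts, not
biological fidelity beyond them.

## Problem sizes and numerics

Default analyses use a 150-neuron slice on the 8×8 array.  The packaged
experiments run the pairing protocol at full scale (100 reps) and the
28-ROI sequence assay with a 64×64 px movie at 10 Hz (the movie size is a
rendering resolution, not a model parameter; tests use 32–48 px movies).
Times are integer µs end to end; the codec property tests cover
randomized matrices including simultaneity; degenerate inputs (empty
matrices, empty slices, flat traces, zero-variance assays) return empty
or identity results rather than erroring, except where a patched-cell
readout is requested from a slice without one.
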