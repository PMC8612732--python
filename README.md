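# quantal

Quantitative analysis of tonic-versus-phasic synaptic transmission at the
*Drosophila* larval neuromuscular junction (NMJ), built for physiologists
quantifying how a presynaptic release suppressor (such as the decoy SNARE
Tomosyn) shapes release probability, short-term depression and homeostatic
plasticity. The package bundles five analysis layers behind one API:

* **synth** — a mechanistic stochastic simulator of vesicle release with
  known ground truth, rendering voltage-clamp traces, Ca²⁺-indicator movies
  and EM-style annotations;
* **minis** — detection and quantification of spontaneous miniature
  excitatory junctional currents (mEJCs);
* **evoked** — evoked-response metrics, quantal content, cumulative-charge
  kinetics, Ca²⁺ cooperativity, paired pulses, and 10 Hz train / vesicle-pool
  analysis;
* **imaging** — optical quantal analysis: per-active-zone release
  probability (Pr) maps from postsynaptic indicator movies, with paired
  pre/post comparison for homeostatic potentiation experiments;
* **ultrastructure / stats** — EM docking geometry and the group statistics
  used for reporting.

## The model

Each of `n_az` active zones carries `slots_per_az` docking sites. On a
stimulus, an occupied site releases its vesicle with probability

```
p_eff = p_v · (1 − θ)
```

where θ ∈ [0, 1] is an inhibition factor standing in for Tomosyn levels.
Between stimuli an empty site refills with probability ρ, so the occupancy
of a site evolves as `o ← o(1 − p_eff)` then `o ← o + (1 − o)ρ`, with fixed
point

```
o* = ρ / (1 − (1 − p_eff)(1 − ρ))
```

and steady-state release rate `o*·p_eff` per site. High θ produces tonic
output (low initial quantal content, depression index near 1); low θ gives
phasic output (large first response, rapid depression) — the release-record
ground truth drives all downstream renderers. Quantal content is measured
as evoked peak (or charge) over the mean mini amplitude (or area); pool
sizes follow the train convention: IRP = cumulative quanta over 30 stimuli
at 10 Hz, RRP = back-extrapolated intercept of cumulative quanta over the
steady-state tail, recycling rate = tail slope × frequency. Optical Pr is
evoked events per ROI divided by the number of stimulations.

## Worked example

```python
import numpy as np
from quantal.datatypes import StimProtocol
from quantal.synth import (ReleaseModelParams, simulate_release,
                           synthesize_trace, synthesize_mini_trace)
from quantal.minis import detect_minis, summarize_minis
from quantal.evoked import evoked_metrics

# a control-like tonic NMJ: 300 AZs, quantal size 0.58 nA, 2.7 Hz minis
params = ReleaseModelParams(n_az=300, p_v=0.3, rho=0.5, seed=11)

# 60 s of spontaneous recording -> mini frequency and quantal size
mini_trace, _ = synthesize_mini_trace(params, 60.0)
m = summarize_minis(detect_minis(mini_trace), mini_trace.duration)
print(f"minis: {m.n_events} events, {m.frequency:.2f} Hz, "
      f"mean amplitude {m.mean_amplitude:.3f} nA")

# three evoked responses at 0.33 Hz -> quantal content
protocol = StimProtocol.periodic(3, 0.33, start=0.5)
record = simulate_release(params, protocol)
trace = synthesize_trace(record)
ev = evoked_metrics(trace, protocol.stim_times[0], mini_ref=m)
print(f"evoked: peak {ev.peak:.1f} nA, charge {ev.area:.0f} nA*ms, "
      f"t90 {ev.t90:.1f} ms")
print(f"quantal content (peak / mini amplitude): {ev.qc_peak:.1f} quanta")
print(f"true vesicles released on stimulus 1: {record.counts[0].sum()}")
```

prints

```
minis: 158 events, 2.63 Hz, mean amplitude 0.560 nA
evoked: peak 46.8 nA, charge 433 nA*ms, t90 19.7 ms
quantal content (peak / mini amplitude): 83.6 quanta
true vesicles released on stimulus 1: 87
```

The detected mini rate and amplitude recover the generator settings
(2.7 Hz, 0.58 nA) within sampling error; the peak-based quantal content
(83.6) sits a few percent below the true released count (87) because
latency jitter desynchronizes the quantal peaks — the charge-based estimate
avoids that bias and is the default for train analysis.

A command-line layer mirrors the library:
`quantal simulate trace|movie|em`, `quantal minis`, `quantal evoked`,
`quantal train`, `quantal cooperativity`, `quantal prmap`, `quantal em`,
`quantal report` (see `quantal --help`).

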