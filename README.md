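# polychron

An event-driven simulator of **reconfigurable polychronous spiking neural
networks**: networks that store and recall spatio-temporal spike patterns in
their **axonal delays** rather than in synaptic weights.  It is aimed at
computational neuroscientists and neuromorphic engineers who want to study
pattern-memory capacity, cross-talk and delay plasticity in such networks, or
to prototype mixed-signal (analog/digital) realisations of them in software.

## The model

A *polychronous group* is a set of (neuron, time) pairs with a time-locked
relation: spikes travel down axons with specific delays so that they arrive
*simultaneously* at a common target neuron and make it fire, even though the
source neurons fired asynchronously.

The simulated machine has two arrays connected by address-event (AER) buses:

* **Neuron array** — coincidence detectors with 4 input lines that fire when
  at least K = 3 lines receive a pre-synaptic spike within W = 1 ms, followed
  by a refractory period.  Two interchangeable backends implement this: a
  *digital* model (four timers and a comparator, evaluated event-driven) and
  a behavioural *analog* LIF model — per-line synaptic currents that decay
  with τ_syn and drive a first-order membrane filter
  τ_mem·dI_out/dt + I_out = I_P1, firing when I_out crosses a calibrated
  threshold.  A *multiplexed* backend leases a pool of 50 physical neurons to
  4096 virtual addresses for 1 ms at a time.
* **Axon array** — modules with one input address, four output addresses and
  four programmable delay paths.  Training consumes one module per pattern
  spike: the spike becomes the module's input, and the next four pattern
  spikes become its outputs with the observed inter-spike intervals as
  delays; a pattern of S spikes therefore occupies S modules and an array of
  A modules stores ⌊A/S⌋ patterns.  During recall, a post-synaptic spike
  restarts the ramp generator of every module whose input matches, emitting
  pre-synaptic spikes after the stored delays.

Delays are set either by one-shot **delay programming** or by
**spike-timing-dependent delay plasticity (STDDP)**: with timing error
Δ = t_pre-arrival − t_post-fire, a presentation updates the delay by −Δ
(exact), −step·sign(Δ) (fixed step) or −c·Δ (proportional, c = 0.5), so the
error contracts as (1−c)ⁿ.

Addresses on the analog buses are **k-of-n constant-weight codes** — an
address is valid iff exactly N of M wires are HIGH, giving
C(M,N) = M!/(N!(M−N)!) codewords: 56 for the 3-of-8 neuron bus, 126 for the
4-of-9 axon bus.  A three-step synchroniser (two-register sync → popcount
validity latch into a 32-deep FIFO → fixed-width regeneration) recovers
spikes from skewed, glitchy asynchronous waveforms without a handshake; the
`aer` module models both the imperfect bus and the sampler.

A pattern is recalled by injecting its first 3 spikes; recall is scored by
the fraction of remaining spikes reproduced within 1 ms of their stored
times (success at ≥ 95%), and runaway cross-talk is flagged as the
*all-firing* state.

## Worked example

Store five cross-talk-free 20-spike patterns on a 126-neuron network with a
100-module axon array, then recall each from its first three spikes:

```python
from polychron import (NetworkConfig, PatternSpec, generate_patterns, train,
                       score_recall, summarize)

patterns = generate_patterns(PatternSpec(
    n_patterns=5, n_spikes=20, n_neurons=126, disjoint=True, seed=1))
net = train(NetworkConfig(n_neurons=126, n_axon_modules=100, seed=1), patterns)

metrics = []
for i, p in enumerate(patterns):
    result = net.recall(p)                      # inject the first 3 spikes
    m = score_recall(p, result, n_initiation=3)
    metrics.append(m)
    print(f"pattern {i}: {m.matched}/{m.expected} spikes recalled "
          f"(fraction {m.fraction:.2f}, success {m.success})")
print(summarize(metrics))
```

```
pattern 0: 17/17 spikes recalled (fraction 1.00, success True)
pattern 1: 17/17 spikes recalled (fraction 1.00, success True)
pattern 2: 17/17 spikes recalled (fraction 1.00, success True)
pattern 3: 17/17 spikes recalled (fraction 1.00, success True)
pattern 4: 17/17 spikes recalled (fraction 1.00, success True)
{'n_patterns': 5, 'percent_patterns_recalled': 100.0,
 'mean_percent_spikes_recalled': 100.0, 'any_all_firing': False}
```

Each pattern has 20 spikes; 3 are injected to start the recall and the
remaining 17 are completed by the network at exactly their stored times —
the time-locked relation of a noiseless digital network is perfect.  Cross-
talk between overlapping patterns, Poisson noise injection, analog axon
imperfections and the bus synchroniser can all be switched on through
`NetworkConfig`, `NoiseSpec`, `ImperfectionModel` and `SkewGlitchModel`.

A `polychron` console script exposes the same flow
(`generate`, `train`, `recall`, `sweep`, `report`); see `polychron --help`.

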