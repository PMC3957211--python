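# Methods

## Scope and architecture

`polychron` simulates a reconfigurable polychronous spiking neural network —
a delay-based memory for spatio-temporal spike patterns — at the behavioural
level of its hardware realisation: coincidence-detector neurons, axon
modules with four programmable delay paths each, constant-weight AER
address codes, an asynchronous-bus synchroniser, and a controller that
multiplexes a small pool of physical neurons across a large virtual address
space.  Transistor-level behaviour is out of scope; analog non-idealities
enter only as statistical models (programming offset, emission jitter,
spurious emissions, bus skew and glitches).

The simulation is event-driven: a single priority queue orders spike events
by (time, insertion sequence).  There is no global integration step — the
analog neuron evolves between events by the closed-form solution of its
two-exponential dynamics, and the digital neuron is pure bookkeeping.  This
makes a 4096-neuron, 81920-module recall of 1200 stored patterns run in
seconds per pattern set on one core.

## Neurons

**Digital backend.**  Four per-line timers and a comparator.  An arrival at
time t (re)arms its line's timer to t + W; the neuron fires iff at least K
timers are unexpired (closed window: a timer armed at t − W still counts at
t) and t is outside the refractory period.  Firing clears all timers.
Defaults: 4 lines, K = 3, W = 1 ms, refractory 2 ms.  Firing decisions are
evaluated at arrivals only, matching the timer-plus-comparator semantics.
The refractory duration is a design choice (the hardware circuit is given
but not its time constant); 2 ms exceeds the coincidence window while
remaining far below the 5–15 ms inter-spike intervals, so it never blocks a
legitimate pattern spike.

**Analog backend.**  A behavioural LIF neuron in normalised current units.
A pre-synaptic spike *resets* its line's synaptic current to the full
amplitude (the synapse capacitor is pulled to ground), after which it decays
as e^(−t/τ_syn).  The summed current drives a first-order low-pass membrane,
τ_mem·dI_out/dt + I_out = I_P1, with τ_mem = n·U_T·C_mem/I_t ≈ 0.038 ms from
the translinear-filter device values (n = 1.5, U_T = 25.6 mV, C_mem =
0.6 pF, I_t = 1 nA).  Between events both follow the closed form
I_out(Δ) = c·e^(−Δ/τ_syn) + (I₀ − c)·e^(−Δ/τ_mem) with
c = A·τ_syn/(τ_syn − τ_mem); the post-spike peak position has a closed form
and the threshold crossing on the rising flank is found by bisection
(80 iterations, exact to double precision for practical purposes).  Firing
zeroes I_out and suspends integration for the refractory period, during
which synapses still decay.

**Threshold calibration and τ_syn.**  The firing threshold is calibrated by
bisection so that any three spikes within the 1 ms window fire the neuron
while any two do not.  With reset (non-additive) synapses the strongest
2-spike stimulus is two simultaneous spikes (peak 2·amp) and the weakest
3-in-window stimulus is two spikes at the window start plus one at its end
(peak ≈ (1 + 2e^(−W/τ_syn))·amp), so a separating band exists only for
τ_syn > W/ln 2 ≈ 1.44 ms.  The default is τ_syn = 5 ms, which leaves a
comfortable band (calibrated threshold ≈ 2.27·amp) and gives 100% agreement
with the digital neuron on randomized 3-vs-2 coincidence trials while still
rejecting three spikes spread over 5 ms.  A synapse as fast as the device
values alone would suggest (~0.3 ms) cannot satisfy the coincidence
criterion in this behavioural model, and a unit test pins that fact.  The
analog neuron remains a deliberately *imperfect* coincidence detector: its
decision boundary is a current threshold, not a spike count.

**Multiplexed array.**  A controller maps virtual addresses onto a pool of
physical neurons (default 50 physical / 4096 virtual, an 80× area saving).
A pre-synaptic spike to an unassigned address leases a free neuron, latches
the address and starts a 1 ms expiry timer — one coincidence window.  The
lease is *not* restarted by subsequent spikes (the hardware behaviour is
unstated; restarting would let a busy address monopolise a neuron beyond
its coincidence window).  On expiry the neuron is freed and its state
cleared.  When the pool is exhausted the spike is dropped, counted and
logged — the hardware's behaviour on exhaustion is likewise unstated, and
dropping mirrors a bus with nobody listening.  Fires are stamped with the
latched virtual address; firing from an unassigned neuron is an internal
error.

## Axons

Training allocates modules strictly in physical order.  Each training spike
(i) becomes the next output address — with the elapsed interval as the
programmed delay — of every earlier module of the *same pattern* that still
has fewer than four outputs, and (ii) latches a freshly allocated module's
input address.  Pattern boundaries close the open modules, so the trailing
modules of a pattern keep fewer than four outputs and patterns never share
modules.  Exhausting the array raises a capacity error naming the pattern.

Delays are continuous floats in (0, max_delay] with max_delay = 100 ms (the
ramp range is not quantified by the hardware; 100 ms covers four maximal
15 ms inter-spike intervals with headroom).  An optional quantization grid
(0.1 ms suggested) emulates a counter-based digital ramp; it is off by
default.  Recall emission: a matching post-synaptic spike restarts the
module's ramp; each configured path j emits at t + delay_j on active line j.
A re-trigger while a ramp runs cancels the not-yet-emitted events of the
previous trigger (tracked by a per-module generation counter) — the
hardware behaviour here is unstated, and cancelling prevents unbounded
event inflation.

**STDDP.**  With Δ = t_pre-arrival − t_post-fire, one presentation updates
the delay by −Δ (exact), −step·sign(Δ) (fixed step, default 0.1 ms) or
−c·Δ (proportional, default c = 0.5, halving the error each presentation).
Results are clamped to (0, max_delay].  During a training presentation the
whole pattern is driven externally, so every neuron fires at its stored
time; each path's arrival is paired with the fire of the neuron whose
address that path latched (by stored position, which is pairing by address
since a neuron fires once per presentation).  An arrival whose neuron did
not fire leaves the delay unchanged.  A ±1 ms pairing window was considered
and rejected: with random initial delays over (0, 100] ms it would almost
never pair, and adaptation from random initialisation — which the training
procedure requires — could not converge.

**Imperfection model** (analog axon emulation): programming multiplies the
stored delay by (1 + ε), ε ~ N(0, σ) with σ = 0.10; every emission adds
jitter uniform in ±0.3 ms (ramp noise, persisting after adaptation); an
optional probability of a spurious emission on a neighbouring path models
parasitic coupling (default 0).  The analog training schedule is delay
programming followed by fixed-step adaptation (default 20 iterations of
0.1 ms); because each measured arrival carries the jitter, adaptation
converges only to within roughly the residual bound plus one step.

## AER buses and the synchroniser

Codebooks enumerate all C(M,N) weight-N words of width M in lexicographic
bit-vector order (index 0 = smallest); the router's four look-up tables
(binary ↔ 3-of-8, binary ↔ 4-of-9) are built from this ordering.  Decoding
validates the popcount, so an all-zeros or overweight word is rejected.

The waveform synthesiser renders each spike as pulses (default 1 μs) on its
N address wires plus one active line, with fixed per-wire skew offsets
(uniform in [0, 20 ns] — the "tens of nanoseconds" regime), per-pulse width
jitter (±10 ns), and glitches: Poisson-count pulses of 5–30 ns placed on
idle wires *within the driven plateau* of a pulse, behind a guard band
around the rise/fall skew bands, at 0.3 glitches per microsecond of driven
bus time.  Placing glitches on the plateau reflects their origin in
capacitive coupling to driven lines; glitches coinciding with a partial
rise/fall transition are not modelled — in that regime a glitch could
complete a wrong valid word, something the measured hardware never
exhibited.  Under this model wrong addresses are structurally impossible
(plateau glitch ⇒ popcount N+1 ⇒ invalid ⇒ back to the same word), while
glitch-induced *duplicate* samples of the same address emerge at a ~20%
rate, the same regime as the hardware's ~25%; the exact split is
hardware-dependent and only the duplicates-are-benign property is asserted.

The sampler (default 50 MHz clock, 32-deep FIFO) implements the three
steps: two-register synchronisation (two-tick delay per wire), popcount
latch conditions — (1) count becomes N after not-N, (2) a different valid
address replaces a valid one, (3) on the multi-active-line bus, the same
address with a *changed, nonzero* active-line code (a change to zero is the
end of a spike, not a new one) — and FIFO drain at one entry per four clock
cycles.  Active-line bits may settle a tick or two after the address
completes under skew; the latch reads them over the following ≤ 3 ticks.
FIFO overflow raises an error carrying the number of dropped entries.  An
optional dedup timer (off by default, as in the hardware) suppresses
re-latching the same address within 1 μs.

## Synthetic patterns, noise and scoring

Patterns draw spike addresses uniformly over the network with no neuron
repeated within any five consecutive spikes, and inter-spike intervals
i.i.d. uniform in 5–15 ms (51 spikes ≈ 500 ms ≈ 100 spikes/s, the reference
firing-rate regime).  Disjoint mode partitions the neuron population across
patterns for cross-talk-free measurements.  The exact hardware generator is
an LFSR whose taps are unpublished; a seeded PCG64 stream replaces it.
Noise is a homogeneous Poisson process at the network level (2–128 extra
spikes per second across the whole network), each event hitting a uniform
neuron on a uniform synapse line; noise is injected during recall only.

Recall injects the pattern's first 3 spikes (the minimum delivering a full
K = 3 coincidence to the next neuron in the chain; the hardware's exact
initiation count is unstated) and runs to quiescence or to
t₀ + duration + 10·max_delay.  Scoring matches each remaining stored spike
greedily, one-to-one and in time order, to an emitted spike of the same
neuron within ±1 ms (the coincidence window; the hardware's scoring
tolerance is unstated); a pattern succeeds at ≥ 95% matched, and never
succeeds if the run was flagged all-firing.  The all-firing flag trips when
the network emits more than 5× the expected spike count — the state is
described only qualitatively in the hardware experiments, and 5× separates
it unambiguously from normal recall (which cannot exceed ~1× for disjoint
patterns and rarely exceeds ~2× with cross-talk).

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on arrays of 4–100 modules and 6–128 neurons.
The end-to-end experiments use the study conditions themselves: the size
sweep trains 82 patterns × 51 spikes (one module per spike, 4182 modules)
on 128–512 neurons (10 seeded runs at 256); the capacity experiment trains
1200 patterns × 51 spikes on 4096 neurons / 81920 modules (3 seeded runs);
the interface stress test sends 50 addresses × 128 repetitions × 10 runs;
the analog-emulation comparison fills a 100-module array at lengths 20 and
50 over 12–20 seeded runs.  The full suite completes in a couple of minutes
on one core.

## Known limitations

* The digital backend is *idealised*: continuous time, no FPGA timing
  granularity, no time-multiplexing contention, no physical-neuron sharing.
  Consequently, at the cross-talk criticality edge its recall rates are
  upper bounds: a 256-neuron network at full load recalls essentially all
  patterns here, whereas real hardware at that size reports ~80% — recall
  there collapses over a narrow range of effective timing resolution (with
  the optional delay quantization: 0.25 ms ≈ 99%, 0.5 ms ≈ 59%,
  1 ms ≈ 11% and all-firing).  The qualitative shape — all-firing at 128
  neurons, ceiling from 512 up — reproduces.
* Synchroniser flip-flop metastability, charge-injection physics, on-chip
  parasitic coupling between neighbouring neurons/axons, power and layout
  are not modelled; transition-coincident glitches are excluded by
  construction (see above).
* The analog imperfection model's 10% *relative* programming error on
  delays up to 60 ms produces much larger absolute errors than the hardware
  exhibits against its 1 ms coincidence window, so absolute spike-recall
  fractions in the analog-axon emulation are far below the hardware's
  ~86%; the emulation is used for directional comparisons (longer patterns
  degrade; adaptation helps) only.
* Adaptation-mode training with the reference 5 presentations from
  full-range random delays leaves residual errors around |err₀|/32 ≈ 1 ms —
  at the edge of the coincidence window — so end-to-end recall after only 5
  presentations is poor unless the initial range is narrowed or more
  presentations are used (~20 suffice for exact recovery).
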