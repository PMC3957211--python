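"""Coincidence-detector neuron backends and the virtual-neuron controller.

Every neuron in the network is a coincidence detector with four input lines
that fires when at least K (default 3) lines receive a pre-synaptic spike
within a short window W (default 1 ms).  Two backends implement this:

* the *digital* model — four per-line timers and one comparator, evaluated
  event-driven at each arrival;
* the *analog* model — a behavioural leaky integrate-and-fire neuron: each
  line drives a charge-and-discharge synapse whose current decays with
  ``tau_syn``; the summed synaptic current feeds a first-order low-pass
  membrane filter ``tau_mem * dI_out/dt + I_out = I_P1`` and the neuron fires
  when I_out crosses a threshold.  Between events both follow closed-form
  two-exponential updates, so no fixed-step integration is needed.

The multiplexed array leases a small pool of physical neurons (default 50) to
virtual addresses for the duration of the coincidence window (1 ms lease),
which lets e.g. 4096 virtual neurons share 50 physical ones.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InternalStateError, SequencingError
from .events import POST_SYNAPTIC, SpikeEvent

log = logging.getLogger(__name__)

__all__ = [
    "DigitalNeuronParams",
    "DigitalNeuronState",
    "digital_on_presyn",
    "DigitalNeuronArray",
    "AnalogNeuronParams",
    "AnalogNeuronState",
    "analog_step",
    "analog_on_presyn",
    "calibrate_threshold",
    "membrane_tau",
    "ControllerState",
    "controller_on_presyn",
    "controller_on_fire",
    "MultiplexedNeuronArray",
]


# ---------------------------------------------------------------------------
# digital timer-based coincidence detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigitalNeuronParams:
    """Four timers and one comparator: fire when >= threshold lines are live."""

    n_lines: int = 4
    threshold: int = 3
    window: float = 1.0  # ms
    refractory: float = 2.0  # ms

    def __post_init__(self):
        if not 1 <= self.threshold <= self.n_lines:
            raise ValueError("need 1 <= threshold <= n_lines")
        if self.window <= 0 or self.refractory < 0:
            raise ValueError("window must be positive, refractory non-negative")


@dataclass
class DigitalNeuronState:
    """Per-line timer expiry times plus refractory bookkeeping."""

    expiry: np.ndarray
    refractory_until: float = -math.inf
    last_time: float = -math.inf

    @classmethod
    def fresh(cls, params: DigitalNeuronParams) -> "DigitalNeuronState":
        return cls(expiry=np.full(params.n_lines, -math.inf))


def digital_on_presyn(
    state: DigitalNeuronState, params: DigitalNeuronParams, t: float, line: int
) -> bool:
    """Deliver a pre-synaptic spike at time ``t`` on ``line``; return fired.

    The line's timer is (re)armed to ``t + window``; the neuron fires iff at
    least ``threshold`` timers are unexpired (closed window: a timer armed at
    ``t - window`` still counts at ``t``) and the neuron is outside its
    refractory period.  Firing clears all timers.
    """
    if t < state.last_time:
        raise SequencingError(f"event at {t} precedes last event {state.last_time}")
    if not 0 <= line < params.n_lines:
        raise ValueError(f"line {line} outside 0..{params.n_lines - 1}")
    state.last_time = t
    state.expiry[line] = t + params.window
    if t >= state.refractory_until and int((state.expiry >= t).sum()) >= params.threshold:
        state.expiry[:] = -math.inf
        state.refractory_until = t + params.refractory
        return True
    return False


class DigitalNeuronArray:
    """Vectorised bank of digital coincidence detectors indexed by address."""

    def __init__(self, n_neurons: int, params: DigitalNeuronParams | None = None):
        self.params = params or DigitalNeuronParams()
        self.n_neurons = n_neurons
        self.expiry = np.full((n_neurons, self.params.n_lines), -math.inf)
        self.refractory_until = np.full(n_neurons, -math.inf)

    def reset(self) -> None:
        self.expiry.fill(-math.inf)
        self.refractory_until.fill(-math.inf)

    def on_presyn(self, address: int, line: int, t: float) -> bool:
        p = self.params
        row = self.expiry[address]
        row[line] = t + p.window
        if t >= self.refractory_until[address] and int((row >= t).sum()) >= p.threshold:
            row[:] = -math.inf
            self.refractory_until[address] = t + p.refractory
            return True
        return False


# ---------------------------------------------------------------------------
# behavioural analog LIF neuron
# ---------------------------------------------------------------------------


def membrane_tau(
    n_slope: float = 1.5,
    u_t_volt: float = 0.0256,
    c_mem_farad: float = 0.6e-12,
    i_t_amp: float = 1e-9,
) -> float:
    """Membrane time constant n*U_T*C_mem/I_t of the low-pass soma, in ms."""
    return n_slope * u_t_volt * c_mem_farad / i_t_amp * 1e3


@dataclass(frozen=True)
class AnalogNeuronParams:
    """Behavioural LIF parameters (normalised current units).

    ``tau_syn`` is the decay constant of the charge-and-discharge synapse:
    a pre-synaptic spike resets its line's current to ``amplitude`` (the
    synapse capacitor is pulled to ground, giving maximal current), after
    which the current decays exponentially.  ``tau_mem`` follows from the
    translinear low-pass soma (defaults: slope 1.5, U_T = 25.6 mV, C_mem =
    0.6 pF, I_t = 1 nA, i.e. ~0.038 ms).  ``threshold`` is normally left
    ``None`` and calibrated with :func:`calibrate_threshold` so that three
    spikes inside 1 ms fire the neuron and two do not.
    """

    n_lines: int = 4
    tau_syn: float = 5.0  # ms
    amplitude: float = 1.0
    tau_mem: float = membrane_tau()
    threshold: float | None = None
    refractory: float = 2.0  # ms
    pulse_width: float = 0.1  # ms, width of the emitted post-synaptic pulse

    def __post_init__(self):
        if self.tau_syn <= 0 or self.tau_mem <= 0:
            raise ValueError("time constants must be positive")
        if abs(self.tau_syn - self.tau_mem) < 1e-9:
            raise ValueError("tau_syn and tau_mem must differ (two-exponential form)")


@dataclass
class AnalogNeuronState:
    """Per-line synaptic currents, membrane output current, refractory clock."""

    i_syn: np.ndarray
    i_out: float = 0.0
    refractory_until: float = -math.inf
    last_time: float = -math.inf
    pending_id: int = 0  # invalidates previously scheduled fire times

    @classmethod
    def fresh(cls, params: AnalogNeuronParams) -> "AnalogNeuronState":
        return cls(i_syn=np.zeros(params.n_lines))


def _filter_coeff(a: float, params: AnalogNeuronParams) -> float:
    """Particular-solution coefficient of the membrane filter for drive a*e^(-t/ts)."""
    ts, tm = params.tau_syn, params.tau_mem
    return a * ts / (ts - tm)


def _i_out_after(i0: float, a: float, dt: float, params: AnalogNeuronParams) -> float:
    """Closed-form membrane output after ``dt`` with initial output ``i0`` and
    total synaptic current ``a`` decaying with tau_syn."""
    ts, tm = params.tau_syn, params.tau_mem
    c = _filter_coeff(a, params)
    return c * math.exp(-dt / ts) + (i0 - c) * math.exp(-dt / tm)


def analog_step(
    state: AnalogNeuronState, params: AnalogNeuronParams, t_prev: float, t_now: float
) -> AnalogNeuronState:
    """Advance the state from ``t_prev`` to ``t_now`` with no input (in place).

    Synaptic currents decay with ``tau_syn``; the membrane output follows the
    first-order filter driven by their sum.  During the refractory period the
    filter does no integration and the output stays at zero.
    """
    if t_now < t_prev:
        raise SequencingError("negative time step")
    dt = t_now - t_prev
    state.last_time = t_now
    if dt == 0:
        return state
    a = float(state.i_syn.sum())
    if t_prev < state.refractory_until:
        span = min(t_now, state.refractory_until) - t_prev
        state.i_syn *= math.exp(-span / params.tau_syn)
        state.i_out = 0.0
        t_prev += span
        dt = t_now - t_prev
        if dt <= 0:
            state.last_time = t_now
            return state
        a = float(state.i_syn.sum())
    state.i_out = _i_out_after(state.i_out, a, dt, params)
    state.i_syn *= math.exp(-dt / params.tau_syn)
    state.last_time = t_now
    return state


def _next_crossing(
    state: AnalogNeuronState, params: AnalogNeuronParams, threshold: float
) -> float | None:
    """Time offset of the next upward threshold crossing, assuming no further
    input, or None if the membrane peak stays below threshold."""
    i0 = state.i_out
    a = float(state.i_syn.sum())
    if i0 >= threshold:
        return 0.0
    c = _filter_coeff(a, params)
    if c <= i0:  # output only decays from here
        return None
    ts, tm = params.tau_syn, params.tau_mem
    # peak of the two-exponential response
    ratio = (c - i0) * ts / (c * tm)
    if ratio <= 1.0:
        d_peak = 0.0
    else:
        d_peak = math.log(ratio) / (1.0 / tm - 1.0 / ts)
    if _i_out_after(i0, a, d_peak, params) < threshold:
        return None
    # bisect the rising flank for the crossing time
    lo, hi = 0.0, d_peak
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _i_out_after(i0, a, mid, params) >= threshold:
            hi = mid
        else:
            lo = mid
    return hi


def analog_on_presyn(
    state: AnalogNeuronState,
    params: AnalogNeuronParams,
    t: float,
    line: int,
) -> bool:
    """Deliver a pre-synaptic spike; return True if the neuron fires.

    The spike resets its line's synapse to full amplitude.  The neuron fires
    if the membrane output crosses threshold before decaying away (the
    crossing may trail the spike by a fraction of ``tau_mem``); firing zeroes
    the output and starts the refractory period.  ``state.last_fire_offset``
    is not tracked here — use :class:`AnalogNeuron` for scheduled fire times.
    """
    if params.threshold is None:
        raise ValueError("threshold not set; calibrate_threshold() first")
    if t < state.last_time:
        raise SequencingError(f"event at {t} precedes last event {state.last_time}")
    analog_step(state, params, state.last_time if state.last_time > -math.inf else t, t)
    state.i_syn[line] = params.amplitude
    if t < state.refractory_until:
        return False
    dt = _next_crossing(state, params, params.threshold)
    if dt is None:
        return False
    # fire: advance to the crossing, reset output, enter refractory
    analog_step(state, params, t, t + dt)
    state.i_out = 0.0
    state.refractory_until = t + dt + params.refractory
    state.last_time = t + dt
    return True


class AnalogNeuron:
    """Event-driven wrapper that exposes *when* the neuron will fire.

    ``on_presyn`` returns the predicted fire time (absolute) or None; callers
    schedule it and must confirm with ``confirm_fire`` carrying the pending
    id, since a later arrival reschedules an earlier crossing.
    """

    def __init__(self, params: AnalogNeuronParams):
        if params.threshold is None:
            params = calibrate_threshold(params)
        self.params = params
        self.state = AnalogNeuronState.fresh(params)

    def reset(self) -> None:
        self.state = AnalogNeuronState.fresh(self.params)

    def on_presyn(self, t: float, line: int) -> tuple[float, int] | None:
        st, p = self.state, self.params
        if st.last_time > -math.inf and t < st.last_time:
            raise SequencingError("out-of-order arrival")
        analog_step(st, p, st.last_time if st.last_time > -math.inf else t, t)
        st.i_syn[line] = p.amplitude
        if t < st.refractory_until:
            return None
        dt = _next_crossing(st, p, p.threshold)
        if dt is None:
            return None
        st.pending_id += 1
        return t + dt, st.pending_id

    def confirm_fire(self, t: float, pending_id: int) -> bool:
        st, p = self.state, self.params
        if pending_id != st.pending_id or t < st.refractory_until:
            return False
        analog_step(st, p, st.last_time if st.last_time > -math.inf else t, t)
        if st.i_out < p.threshold * (1 - 1e-9):
            return False
        st.i_out = 0.0
        st.refractory_until = t + p.refractory
        st.pending_id += 1
        return True


def _peak_response(params: AnalogNeuronParams, spike_times: list[float]) -> float:
    """Exact membrane peak for spikes on distinct lines at the given times."""
    p = params
    st = AnalogNeuronState.fresh(p)
    peak = 0.0
    times = sorted(spike_times)
    t_prev = times[0]
    for i, t in enumerate(times):
        analog_step(st, p, t_prev, t)
        st.i_syn[i % p.n_lines] = p.amplitude
        t_prev = t
    # trace the tail after the last spike
    a = float(st.i_syn.sum())
    i0 = st.i_out
    c = _filter_coeff(a, p)
    ts, tm = p.tau_syn, p.tau_mem
    if c > i0:
        ratio = (c - i0) * ts / (c * tm)
        d_peak = math.log(ratio) / (1.0 / tm - 1.0 / ts) if ratio > 1 else 0.0
        peak = _i_out_after(i0, a, d_peak, p)
    else:
        peak = i0
    return peak


def calibrate_threshold(
    params: AnalogNeuronParams, window: float = 1.0
) -> AnalogNeuronParams:
    """Bisect a firing threshold separating 3-in-window from 2-spike inputs.

    The hardest 3-spike stimulus inside the window is two spikes at its start
    and one at its end; the strongest 2-spike stimulus is two simultaneous
    spikes.  The returned params carry the midpoint of the separating band;
    a band only exists when ``tau_syn`` is long enough (roughly > W/ln 2).
    """
    worst3 = _peak_response(params, [0.0, 0.0, window])
    best2 = _peak_response(params, [0.0, 0.0])
    if worst3 <= best2:
        raise ValueError(
            f"tau_syn={params.tau_syn} cannot separate 3-in-{window}ms from 2 spikes"
        )
    lo, hi = best2, worst3
    for _ in range(60):  # bisection to the midpoint of the separating band
        mid = 0.5 * (lo + hi)
        gap_lo, gap_hi = mid - best2, worst3 - mid
        if gap_lo < gap_hi:
            lo = mid
        else:
            hi = mid
    return AnalogNeuronParams(
        n_lines=params.n_lines,
        tau_syn=params.tau_syn,
        amplitude=params.amplitude,
        tau_mem=params.tau_mem,
        threshold=0.5 * (lo + hi),
        refractory=params.refractory,
        pulse_width=params.pulse_width,
    )


# ---------------------------------------------------------------------------
# multiplexed (virtual) neuron controller
# ---------------------------------------------------------------------------


@dataclass
class ControllerState:
    """Dynamic map from virtual addresses to a fixed pool of physical neurons.

    Each assignment holds for a fixed ``lease`` (1 ms, the coincidence
    window) that is *not* restarted by subsequent spikes; expired neurons
    return to the free list.  Spikes arriving with no free neuron are dropped
    and counted.
    """

    pool_size: int = 50
    lease: float = 1.0  # ms
    n_virtual: int = 4096
    assignment: dict[int, int] = field(default_factory=dict)  # virtual -> physical
    latched: dict[int, int] = field(default_factory=dict)  # physical -> virtual
    expiry_heap: list[tuple[float, int]] = field(default_factory=list)
    free: list[int] = field(default_factory=list)
    drops: int = 0
    assignments_made: int = 0
    expiries: int = 0

    def __post_init__(self):
        if not self.free and not self.latched:
            self.free = list(range(self.pool_size - 1, -1, -1))

    def expire(self, t: float) -> list[int]:
        """Release all leases that have ended by time ``t``; return freed ids."""
        freed = []
        while self.expiry_heap and self.expiry_heap[0][0] <= t:
            _, phys = heapq.heappop(self.expiry_heap)
            virt = self.latched.pop(phys, None)
            if virt is not None:
                self.assignment.pop(virt, None)
                self.free.append(phys)
                freed.append(phys)
                self.expiries += 1
        return freed

    @property
    def n_leased(self) -> int:
        return len(self.latched)


def controller_on_presyn(
    ctrl: ControllerState, event: SpikeEvent, t: float
) -> tuple[int | None, bool]:
    """Route a pre-synaptic spike to its physical neuron, leasing one if needed.

    Returns ``(physical_index, newly_assigned)``; ``(None, False)`` when the
    pool is exhausted (the spike is dropped and counted).
    """
    ctrl.expire(t)
    virt = event.address
    if not 0 <= virt < ctrl.n_virtual:
        raise InternalStateError(f"virtual address {virt} outside 0..{ctrl.n_virtual - 1}")
    phys = ctrl.assignment.get(virt)
    if phys is not None:
        return phys, False
    if not ctrl.free:
        ctrl.drops += 1
        log.warning("neuron pool exhausted at t=%.3f ms; spike to %d dropped", t, virt)
        return None, False
    phys = ctrl.free.pop()
    ctrl.assignment[virt] = phys
    ctrl.latched[phys] = virt
    heapq.heappush(ctrl.expiry_heap, (t + ctrl.lease, phys))
    ctrl.assignments_made += 1
    return phys, True


def controller_on_fire(ctrl: ControllerState, physical: int, t: float) -> SpikeEvent:
    """Stamp a physical neuron's fire with its latched virtual address."""
    virt = ctrl.latched.get(physical)
    if virt is None:
        raise InternalStateError(f"physical neuron {physical} fired while unassigned")
    return SpikeEvent(time=t, address=virt, line=POST_SYNAPTIC)


class MultiplexedNeuronArray:
    """Virtual coincidence-detector array over a small physical pool.

    ``pool_backend`` selects the physical neuron model ("digital" or
    "analog").  The digital pool fires at arrival time; the analog pool, used
    here with its calibrated threshold, fires within a fraction of tau_mem of
    the third coincident arrival, which this wrapper treats as immediate.
    """

    def __init__(
        self,
        n_virtual: int,
        pool_size: int = 50,
        lease: float = 1.0,
        pool_backend: str = "analog",
        digital_params: DigitalNeuronParams | None = None,
        analog_params: AnalogNeuronParams | None = None,
    ):
        self.ctrl = ControllerState(pool_size=pool_size, lease=lease, n_virtual=n_virtual)
        self.pool_backend = pool_backend
        if pool_backend == "digital":
            self.params = digital_params or DigitalNeuronParams()
            self.pool = [DigitalNeuronState.fresh(self.params) for _ in range(pool_size)]
        elif pool_backend == "analog":
            params = analog_params or AnalogNeuronParams()
            if params.threshold is None:
                params = calibrate_threshold(params)
            self.params = params
            self.pool = [AnalogNeuron(params) for _ in range(pool_size)]
        else:
            raise ValueError(f"unknown pool backend {pool_backend!r}")
        self.n_virtual = n_virtual

    def reset(self) -> None:
        pool_size, lease = self.ctrl.pool_size, self.ctrl.lease
        drops = 0
        self.ctrl = ControllerState(pool_size=pool_size, lease=lease, n_virtual=self.n_virtual)
        self.ctrl.drops = drops
        for neuron in self.pool:
            if isinstance(neuron, DigitalNeuronState):
                neuron.expiry.fill(-math.inf)
                neuron.refractory_until = -math.inf
                neuron.last_time = -math.inf
            else:
                neuron.reset()

    def _fresh_physical(self, phys: int) -> None:
        if self.pool_backend == "digital":
            st = self.pool[phys]
            st.expiry.fill(-math.inf)
            st.refractory_until = -math.inf
            st.last_time = -math.inf
        else:
            self.pool[phys].reset()

    def on_presyn(self, address: int, line: int, t: float) -> bool:
        phys, new = controller_on_presyn(self.ctrl, SpikeEvent(t, address, line), t)
        if phys is None:
            return False
        if new:
            self._fresh_physical(phys)
        if self.pool_backend == "digital":
            fired = digital_on_presyn(self.pool[phys], self.params, t, line)
        else:
            st = self.pool[phys].state
            pending = self.pool[phys].on_presyn(t, line)
            fired = False
            if pending is not None:
                t_fire, pid = pending
                # leases last one coincidence window; treat near-immediate
                # crossings (within the lease) as fires at the crossing time
                if t_fire <= t + self.ctrl.lease:
                    fired = self.pool[phys].confirm_fire(t_fire, pid)
        if fired:
            controller_on_fire(self.ctrl, phys, t)  # validates the lease
        return fired

    @property
    def drops(self) -> int:
        return self.ctrl.drops
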