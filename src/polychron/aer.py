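"""Constant-weight (k-of-n) AER address codes and the asynchronous-bus model.

The analog arrays communicate spikes as addresses on a shared bus with no
handshake and no arbiter: an address is valid whenever exactly N of the M
address wires are HIGH, and one or more *active lines* flag that a spike is
present (one active line per target synapse on the pre-synaptic bus).  The
neuron bus uses a 3-of-8 code (56 addresses); the axon bus uses 4-of-9
(126 addresses).

Because the sender is asynchronous, the receiving clock domain sees per-wire
timing skew and brief coupling glitches.  :func:`synthesize_bus_waveform`
produces such waveforms and :func:`sample_bus` models the three-step
synchroniser (two-register sync, popcount validity latch into a FIFO,
fixed-width spike regeneration) that recovers clean spikes from them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BusOverflowError, BusOverlapError, CodeLookupError, CodeSpecError
from .events import SpikeEvent

__all__ = [
    "CodeSpec",
    "Codebook",
    "SkewGlitchModel",
    "BusWaveform",
    "SampledSpike",
    "n_addresses",
    "build_codebook",
    "synthesize_bus_waveform",
    "sample_bus",
    "NEURON_BUS",
    "AXON_BUS",
]


@dataclass(frozen=True)
class CodeSpec:
    """A k-of-n constant-weight code: ``weight`` of ``width`` wires HIGH."""

    width: int
    weight: int

    def __post_init__(self):
        if not (0 < self.weight < self.width):
            raise CodeSpecError(
                f"need 0 < weight < width, got weight={self.weight}, width={self.width}"
            )


#: 3-of-8 code of the analog neuron array bus (56 addresses).
NEURON_BUS = CodeSpec(width=8, weight=3)
#: 4-of-9 code of the analog axon array bus (126 addresses).
AXON_BUS = CodeSpec(width=9, weight=4)


def n_addresses(spec: CodeSpec) -> int:
    """Number of valid addresses, the binomial coefficient C(width, weight)."""
    return math.comb(spec.width, spec.weight)


def _word_mask(bits: Sequence[int]) -> int:
    """Pack a bit-vector (wire 0 first) into an int with wire i at bit i."""
    mask = 0
    for i, b in enumerate(bits):
        if b:
            mask |= 1 << i
    return mask


class Codebook:
    """Deterministic bijection between indices [0, C(M,N)) and codewords.

    Codewords are enumerated in lexicographic order of their bit-vectors
    (wire 0 compared first), so index 0 is the lexicographically smallest
    word, which has its HIGH bits on the last ``weight`` wires.
    """

    def __init__(self, spec: CodeSpec):
        self.spec = spec
        m, n = spec.width, spec.weight
        vectors = []
        for ones in itertools.combinations(range(m), n):
            bits = [0] * m
            for p in ones:
                bits[p] = 1
            vectors.append(tuple(bits))
        vectors.sort()
        self.words = np.array(vectors, dtype=np.uint8)
        self.masks = np.array([_word_mask(v) for v in vectors], dtype=np.int64)
        self._inverse = {int(msk): i for i, msk in enumerate(self.masks)}

    def __len__(self) -> int:
        return len(self.words)

    def encode(self, index: int) -> np.ndarray:
        """Codeword (bit-vector, wire 0 first) for an address index."""
        if not 0 <= index < len(self):
            raise CodeLookupError(f"address index {index} out of range [0, {len(self)})")
        return self.words[index].copy()

    def decode(self, word) -> int:
        """Address index of a codeword given as bit sequence or packed mask."""
        if isinstance(word, (int, np.integer)):
            mask = int(word)
        else:
            mask = _word_mask(np.asarray(word).astype(int))
        try:
            return self._inverse[mask]
        except KeyError:
            raise CodeLookupError(
                f"invalid codeword (popcount != {self.spec.weight}): mask={mask:#x}"
            ) from None

    def wires(self, index: int) -> np.ndarray:
        """Indices of the HIGH wires of an address."""
        return np.nonzero(self.words[index])[0]


def build_codebook(spec: CodeSpec) -> Codebook:
    return Codebook(spec)


# ---------------------------------------------------------------------------
# bus waveforms
# ---------------------------------------------------------------------------


@dataclass
class SkewGlitchModel:
    """Analog-bus imperfections: per-wire skew, width jitter and glitches.

    Times are microseconds.  Skew offsets are fixed per wire (process
    variation and track-length differences), drawn uniformly in
    [0, ``skew_max``] from ``seed``.  Glitches are brief pulses coupled onto
    idle wires while the bus is being driven; ``glitch_rate`` is the expected
    number of glitches per microsecond of driven bus time.  Glitch widths are
    tens of nanoseconds at most.
    """

    skew_max: float = 0.02
    glitch_rate: float = 0.3
    glitch_width: tuple[float, float] = (0.005, 0.03)
    pulse_jitter: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.skew_max < 0 or self.pulse_jitter < 0 or self.glitch_rate < 0:
            raise ValueError("skew, jitter and glitch rate must be non-negative")
        lo, hi = self.glitch_width
        if not (0 <= lo <= hi):
            raise ValueError("glitch width bounds must be non-negative and ordered")

    def wire_offsets(self, n_wires: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.uniform(0.0, self.skew_max, n_wires)

    def rng(self) -> np.random.Generator:
        # separate stream from the offsets so both are reproducible
        return np.random.default_rng((self.seed, 1))


@dataclass
class BusWaveform:
    """Per-wire pulse trains: wires 0..M-1 are address bits, then L active lines.

    Each wire holds an (n, 2) array of (rise, fall) times in microseconds,
    time-ordered and non-overlapping.
    """

    wires: list[np.ndarray]
    n_address: int
    n_active: int

    def __post_init__(self):
        for w, pulses in enumerate(self.wires):
            pulses = np.asarray(pulses, dtype=np.float64).reshape(-1, 2)
            flat = pulses.ravel()
            if len(flat) and not np.all(np.diff(flat) > 0):
                raise ValueError(f"pulses on wire {w} overlap or are unordered")
            self.wires[w] = pulses

    @property
    def duration(self) -> float:
        ends = [p[-1, 1] for p in self.wires if len(p)]
        return max(ends) if ends else 0.0


def _merge_pulses(pulses: list[tuple[float, float]]) -> np.ndarray:
    """Union of intervals, returned sorted and non-overlapping."""
    if not pulses:
        return np.empty((0, 2))
    pulses.sort()
    merged = [list(pulses[0])]
    for r, f in pulses[1:]:
        if r <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], f)
        else:
            merged.append([r, f])
    return np.array(merged)


def synthesize_bus_waveform(
    events: Sequence[SpikeEvent],
    book: Codebook,
    pulse_width: float = 1.0,
    model: SkewGlitchModel | None = None,
    n_active_lines: int = 1,
) -> BusWaveform:
    """Render time-sorted spike events as per-wire bus pulses.

    Each event raises its codeword's N address wires plus its active line for
    ``pulse_width`` microseconds, with per-wire skew and width jitter when a
    :class:`SkewGlitchModel` is given.  Glitches are injected on idle wires
    during the driven plateaus of the pulses, away from the rise/fall skew
    bands (coupling glitches produced *during* a partial transition are not
    modelled; see the methods note).
    """
    m = book.spec.width
    n_wires = m + n_active_lines
    times = np.array([e.time for e in events], dtype=np.float64)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise BusOverlapError("events must be strictly time-sorted")
    margin = 0.0
    if model is not None:
        margin = model.skew_max + model.pulse_jitter
    if len(times) > 1 and np.any(np.diff(times) <= pulse_width + margin):
        raise BusOverlapError(
            f"inter-event gap must exceed pulse width {pulse_width} + skew/jitter"
        )

    offsets = np.zeros(n_wires)
    rng = None
    if model is not None:
        offsets = model.wire_offsets(n_wires)
        rng = model.rng()

    per_wire: list[list[tuple[float, float]]] = [[] for _ in range(n_wires)]
    for ev in events:
        if not 0 <= ev.line < n_active_lines:
            raise ValueError(f"event line {ev.line} outside 0..{n_active_lines - 1}")
        high = list(book.wires(ev.address)) + [m + ev.line]
        for w in high:
            width = pulse_width
            if rng is not None and model.pulse_jitter > 0:
                width += rng.uniform(-model.pulse_jitter, model.pulse_jitter)
            rise = ev.time + offsets[w]
            per_wire[w].append((rise, rise + width))

    # transition-coupled glitches on idle wires, inside the safe plateau
    if rng is not None and model.glitch_rate > 0 and len(events):
        lo, hi = model.glitch_width
        guard = model.skew_max + model.pulse_jitter + hi
        span = pulse_width - 2 * guard
        if span > 0:
            total_driven = len(events) * pulse_width
            n_glitch = rng.poisson(model.glitch_rate * total_driven)
            for _ in range(n_glitch):
                ev = events[int(rng.integers(len(events)))]
                high = set(book.wires(ev.address).tolist()) | {m + ev.line}
                low = [w for w in range(n_wires) if w not in high]
                w = low[int(rng.integers(len(low)))]
                start = ev.time + guard + rng.uniform(0.0, span)
                per_wire[w].append((start, start + rng.uniform(lo, hi)))

    wires = [_merge_pulses(p) for p in per_wire]
    return BusWaveform(wires=wires, n_address=m, n_active=n_active_lines)


# ---------------------------------------------------------------------------
# three-step synchroniser / sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampledSpike:
    """A spike recovered by the synchroniser: latch tick, address, active lines."""

    tick: int
    address: int
    active_lines: int  # bitmask, line i at bit i

    @property
    def lines(self) -> tuple[int, ...]:
        return tuple(i for i in range(32) if self.active_lines >> i & 1)


def sampled_to_frame(spikes: Sequence[SampledSpike]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tick": [s.tick for s in spikes],
            "address_index": [s.address for s in spikes],
            "active_lines": [s.active_lines for s in spikes],
        }
    )


def write_sampled(path, spikes: Sequence[SampledSpike]) -> None:
    sampled_to_frame(spikes).to_csv(path, index=False)


def sample_bus(
    wave: BusWaveform,
    book: Codebook,
    clock_hz: float = 50e6,
    fifo_depth: int = 32,
    n_active_lines: int = 1,
    dedup_window: float | None = None,
) -> list[SampledSpike]:
    """Recover spikes from a skewed/glitched waveform without a handshake.

    Step 1: every wire goes through a two-register synchroniser (two clock
    delays).  Step 2: a popcount counter watches the synchronised address
    wires; the 9 (or 13) synchronised bits are latched into the FIFO when
    (1) the count becomes exactly N after not being N, (2) one valid address
    is replaced by a different valid address, or — on the multi-active-line
    axon bus — (3) the same valid address re-appears with different active
    lines.  An unchanged valid address is otherwise ignored.  Step 3: the
    FIFO is drained into fixed-width output spikes, one every four clock
    cycles.

    ``dedup_window`` (microseconds), off by default, suppresses re-latching
    the same address within the window — the optional guard timer against
    glitch-induced double sampling.
    """
    if clock_hz <= 0:
        raise ValueError("clock must be positive")
    if wave.n_active < n_active_lines:
        raise ValueError("waveform has fewer active lines than requested")
    period = 1e6 / clock_hz  # microseconds per tick
    n = book.spec.weight
    m = wave.n_address
    n_ticks = int(math.ceil(wave.duration / period)) + 8
    tick_times = np.arange(n_ticks) * period

    # wire state at each tick: inside a pulse iff an odd number of edges passed
    state = np.zeros((len(wave.wires), n_ticks), dtype=bool)
    for w, pulses in enumerate(wave.wires):
        if len(pulses):
            state[w] = np.searchsorted(pulses.ravel(), tick_times, side="right") % 2 == 1

    # step 1: two-register synchroniser = two-tick delay
    sync = np.zeros_like(state)
    sync[:, 2:] = state[:, :-2]

    addr_bits = sync[:m]
    counts = addr_bits.sum(axis=0)
    weights = (1 << np.arange(m, dtype=np.int64))[:, None]
    addr_code = (addr_bits * weights).sum(axis=0)
    act_bits = sync[m : m + n_active_lines]
    act_code = (
        (act_bits * (1 << np.arange(n_active_lines, dtype=np.int64))[:, None]).sum(axis=0)
        if n_active_lines
        else np.zeros(n_ticks, dtype=np.int64)
    )

    valid = counts == n
    v_prev = np.roll(valid, 1)
    v_prev[0] = False
    a_prev = np.roll(addr_code, 1)
    l_prev = np.roll(act_code, 1)

    cond1 = valid & ~v_prev
    cond2 = valid & v_prev & (addr_code != a_prev)
    latch = cond1 | cond2
    if n_active_lines > 1:
        # a change of active line signals a new spike; the lines merely
        # falling back to zero does not
        cond3 = valid & v_prev & (addr_code == a_prev) & (act_code != l_prev) & (act_code != 0)
        latch |= cond3
    ticks = np.nonzero(latch)[0]

    # step 3 bookkeeping: one FIFO entry drained per four clock cycles
    out: list[SampledSpike] = []
    dropped = 0
    pop_ticks: list[int] = []
    last_latched: tuple[int, int] | None = None  # (tick, address) for dedup
    for k in ticks:
        k = int(k)
        address = book.decode(int(addr_code[k]))
        if dedup_window is not None and last_latched is not None:
            t_last, a_last = last_latched
            if address == a_last and (k - t_last) * period <= dedup_window:
                continue
        last_latched = (k, address)
        occupancy = sum(1 for p in pop_ticks if p > k)
        if occupancy >= fifo_depth:
            dropped += 1
            continue
        pop = max(k + 1, (pop_ticks[-1] + 4) if pop_ticks else 0)
        pop_ticks.append(pop)
        # active bits may settle a tick or two after the address completes
        lines = int(act_code[k])
        for look in range(k, min(k + 4, n_ticks)):
            if act_code[look]:
                lines = int(act_code[look])
                break
        out.append(SampledSpike(tick=k, address=address, active_lines=lines))
    if dropped:
        raise BusOverflowError(dropped)
    return out
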