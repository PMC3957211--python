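"""Core event and pattern containers shared by all simulator components.

The network simulation works in milliseconds on *virtual* (binary) neuron
addresses.  The bus-level model in :mod:`polychron.aer` works in microseconds;
it reuses :class:`SpikeEvent` with the time field interpreted in that unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import SequencingError

#: line tag for a post-synaptic spike (a spike emitted by a neuron, travelling
#: to the axon array).  Pre-synaptic spikes carry a synapse line 0..3.
POST_SYNAPTIC = -1


@dataclass(frozen=True)
class SpikeEvent:
    """A timestamped spike carrying a virtual address and a synapse line tag.

    ``line`` is :data:`POST_SYNAPTIC` (-1) for post-synaptic spikes and the
    target synapse index (0-3) for pre-synaptic spikes.
    """

    time: float
    address: int
    line: int = POST_SYNAPTIC

    @property
    def is_presynaptic(self) -> bool:
        return self.line != POST_SYNAPTIC


@dataclass(frozen=True)
class Pattern:
    """An ordered spatio-temporal spike pattern: (neuron, time) pairs.

    Times are strictly increasing milliseconds; by convention the first spike
    is at t = 0.  A pattern is the unit of storage and recall.
    """

    neurons: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        neurons = np.asarray(self.neurons, dtype=np.int64)
        times = np.asarray(self.times, dtype=np.float64)
        if neurons.shape != times.shape or neurons.ndim != 1:
            raise ValueError("neurons and times must be 1-D arrays of equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise SequencingError("pattern spike times must be strictly increasing")
        object.__setattr__(self, "neurons", neurons)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def spikes(self) -> Iterator[tuple[int, float]]:
        return zip(self.neurons.tolist(), self.times.tolist())

    def __iter__(self):
        return self.spikes()


@dataclass
class RecallResult:
    """Output of a recall run.

    ``spikes`` holds only the post-synaptic spikes generated by the network;
    the externally injected initiation spikes are counted in ``injected``.
    """

    spikes: list[tuple[float, int]] = field(default_factory=list)
    injected: int = 0
    all_firing: bool = False
    dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.spikes, columns=["time_ms", "neuron_id"])


# ---------------------------------------------------------------------------
# spike CSV dialect: columns time_ms, neuron_id, line
# ---------------------------------------------------------------------------

def write_spikes(path, events: Sequence[SpikeEvent]) -> None:
    """Write spikes to the package CSV dialect (time_ms, neuron_id, line)."""
    frame = pd.DataFrame(
        {
            "time_ms": [e.time for e in events],
            "neuron_id": [e.address for e in events],
            "line": [e.line for e in events],
        }
    )
    frame.to_csv(path, index=False)


def read_spikes(path) -> list[SpikeEvent]:
    """Read spikes from the package CSV dialect."""
    frame = pd.read_csv(path)
    return [
        SpikeEvent(float(t), int(n), int(l))
        for t, n, l in zip(frame["time_ms"], frame["neuron_id"], frame["line"])
    ]


def pattern_to_events(pattern: Pattern) -> list[SpikeEvent]:
    return [SpikeEvent(t, n, POST_SYNAPTIC) for n, t in pattern.spikes()]


def events_to_pattern(events: Sequence[SpikeEvent]) -> Pattern:
    events = sorted(events, key=lambda e: e.time)
    return Pattern(
        neurons=np.array([e.address for e in events], dtype=np.int64),
        times=np.array([e.time for e in events], dtype=np.float64),
    )
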