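"""Event-driven polychronous network: training and recall over any backend.

The simulator keeps all spikes in a single time-ordered priority queue and
advances event by event — there is no global clock.  Post-synaptic spikes
restart the matching axon modules, whose delay paths schedule pre-synaptic
spikes; pre-synaptic arrivals drive the coincidence-detector neurons, whose
fires are fed back as new post-synaptic spikes.  A stored pattern is
recalled by injecting its first few spikes (default 3, the minimum that
delivers a full threshold-3 coincidence to the next neuron in the chain) and
letting the network complete the rest.

Severe cross-talk drives the network into an *all-firing* state in which
essentially every neuron fires; a run is flagged as all-firing, and stopped,
once the network has emitted more than ``all_firing_factor`` times the
number of spikes the recalled pattern should produce.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import aer
from .axons import AdaptationPolicy, AxonArray, ImperfectionModel
from .errors import RoutingError, SequencingError
from .events import POST_SYNAPTIC, Pattern, RecallResult, SpikeEvent
from .neurons import (
    AnalogNeuron,
    AnalogNeuronParams,
    DigitalNeuronArray,
    DigitalNeuronParams,
    MultiplexedNeuronArray,
    calibrate_threshold,
)

log = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "EventQueue",
    "RouterTables",
    "PolychronousNetwork",
    "train",
    "recall",
    "remap",
]

_POST = 0
_PRE = 1
_FIRE = 2


@dataclass
class NetworkConfig:
    """Study conditions for one network instance.

    ``backend`` is one of ``digital`` (timer/comparator neurons),
    ``analog`` (one behavioural LIF neuron per virtual address) or
    ``multiplexed`` (a physical pool leased to virtual addresses).
    """

    n_neurons: int = 128
    n_axon_modules: int = 4096
    backend: str = "digital"
    pool_size: int = 50
    pool_backend: str = "analog"
    lease: float = 1.0  # ms
    neuron: DigitalNeuronParams = field(default_factory=DigitalNeuronParams)
    analog_neuron: AnalogNeuronParams = field(default_factory=AnalogNeuronParams)
    imperfection: ImperfectionModel | None = None
    policy: AdaptationPolicy = field(default_factory=AdaptationPolicy)
    initiation: int = 3
    max_delay: float = 100.0
    quantization: float | None = None
    all_firing_factor: float = 5.0
    quiescence_slack: float = 10.0  # multiples of max_delay past pattern end
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons <= 0 or self.n_axon_modules <= 0:
            raise ValueError("counts must be positive")
        if self.backend not in ("digital", "analog", "multiplexed"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.initiation < self.neuron.threshold:
            raise ValueError("initiation spike count must reach the firing threshold")

    def to_yaml(self) -> str:
        doc = asdict(self)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        doc = yaml.safe_load(text)
        if doc.get("neuron"):
            doc["neuron"] = DigitalNeuronParams(**doc["neuron"])
        if doc.get("analog_neuron"):
            doc["analog_neuron"] = AnalogNeuronParams(**doc["analog_neuron"])
        if doc.get("imperfection"):
            doc["imperfection"] = ImperfectionModel(**doc["imperfection"])
        if doc.get("policy"):
            doc["policy"] = AdaptationPolicy(**doc["policy"])
        return cls(**doc)


class EventQueue:
    """Priority queue of spike events, ordered by (time, insertion sequence)."""

    def __init__(self):
        self._heap: list[tuple] = []
        self._seq = 0
        self._last_popped = -np.inf

    def push(self, time: float, payload: tuple) -> None:
        heapq.heappush(self._heap, (time, self._seq, payload))
        self._seq += 1

    def pop(self) -> tuple[float, tuple]:
        time, _, payload = heapq.heappop(self._heap)
        if time < self._last_popped:
            raise SequencingError("event queue popped into the past")
        self._last_popped = time
        return time, payload

    def __len__(self) -> int:
        return len(self._heap)

    def __bool__(self) -> bool:
        return bool(self._heap)


class RouterTables:
    """Four look-up tables converting binary addresses to bus codewords.

    Two tables per bus direction: binary <-> 3-of-8 codeword masks for the
    neuron bus (56 addresses) and binary <-> 4-of-9 for the axon bus (126).
    """

    def __init__(
        self,
        neuron_book: aer.Codebook | None = None,
        axon_book: aer.Codebook | None = None,
    ):
        self.neuron_book = neuron_book or aer.build_codebook(aer.NEURON_BUS)
        self.axon_book = axon_book or aer.build_codebook(aer.AXON_BUS)

    def _book(self, direction: str) -> tuple[aer.Codebook, bool]:
        bus, _, way = direction.partition("_")
        if bus not in ("neuron", "axon") or way not in ("encode", "decode"):
            raise ValueError(
                "direction must be one of neuron_encode, neuron_decode, "
                "axon_encode, axon_decode"
            )
        return (self.neuron_book if bus == "neuron" else self.axon_book), way == "encode"


def remap(tables: RouterTables, event: SpikeEvent, direction: str) -> SpikeEvent:
    """Rewrite an event's address through a router table; time and line kept.

    ``direction``: ``neuron_encode`` / ``axon_encode`` turn a binary address
    into the packed codeword mask of the respective bus; the ``*_decode``
    directions invert them.  Addresses outside the table domain raise
    :class:`RoutingError`.
    """
    book, encode = tables._book(direction)
    if encode:
        if not 0 <= event.address < len(book):
            raise RoutingError(
                f"virtual address {event.address} exceeds the {book.spec.weight}/"
                f"{book.spec.width} bus limit of {len(book)} addresses"
            )
        new = int(book.masks[event.address])
    else:
        try:
            new = book.decode(event.address)
        except Exception as exc:
            raise RoutingError(str(exc)) from exc
    return SpikeEvent(time=event.time, address=new, line=event.line)


class PolychronousNetwork:
    """A trained network: an axon array plus a neuron backend."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.axons = AxonArray(
            n_modules=config.n_axon_modules,
            max_delay=config.max_delay,
            quantization=config.quantization,
            imperfection=config.imperfection,
            seed=config.seed,
        )
        self.rng = np.random.default_rng(config.seed)
        self.patterns: list[Pattern] = []
        self._make_backend()

    def _make_backend(self):
        cfg = self.config
        if cfg.backend == "digital":
            self.neurons = DigitalNeuronArray(cfg.n_neurons, cfg.neuron)
        elif cfg.backend == "multiplexed":
            self.neurons = MultiplexedNeuronArray(
                n_virtual=cfg.n_neurons,
                pool_size=cfg.pool_size,
                lease=cfg.lease,
                pool_backend=cfg.pool_backend,
                digital_params=cfg.neuron,
                analog_params=cfg.analog_neuron,
            )
        else:  # analog: one behavioural LIF neuron per virtual address, lazily
            params = cfg.analog_neuron
            if params.threshold is None:
                params = calibrate_threshold(params, window=cfg.neuron.window)
            self._analog_params = params
            self.neurons = {}

    def reset_neurons(self) -> None:
        if isinstance(self.neurons, dict):
            self.neurons.clear()
        else:
            self.neurons.reset()

    # -- training ----------------------------------------------------------

    def train_patterns(
        self,
        patterns: list[Pattern],
        mode: str = "programming",
        presentations: int = 5,
    ) -> "PolychronousNetwork":
        """Store patterns by delay programming or by delay adaptation.

        Programming allocates modules and stores each observed inter-spike
        interval in a single presentation.  Adaptation allocates the same
        address structure but starts from random delays and replays each
        pattern ``presentations`` times (default 5) under the configured
        policy.
        """
        if mode not in ("programming", "adaptation"):
            raise ValueError(f"unknown training mode {mode!r}")
        base = len(self.patterns)
        for i, pattern in enumerate(patterns):
            if np.any(pattern.neurons >= self.config.n_neurons):
                raise ValueError(f"pattern {i} uses neuron ids >= n_neurons")
            self.axons.train_pattern(pattern, program=(mode == "programming"))
        self.patterns.extend(patterns)
        if mode == "adaptation":
            self.axons.randomize_delays(self.rng)
            for _ in range(presentations):
                for i, pattern in enumerate(patterns):
                    self.axons.adapt_on_replay(base + i, pattern, self.config.policy)
        return self

    def adapt(self, presentations: int, policy: AdaptationPolicy | None = None) -> None:
        """Extra noiseless adaptation presentations of every stored pattern
        (the analog schedule: programming first, then fixed-step refinement)."""
        policy = policy or self.config.policy
        for i, pattern in enumerate(self.patterns):
            for _ in range(presentations):
                self.axons.adapt_on_replay(i, pattern, policy)

    # -- recall --------------------------------------------------------------

    def _deliver(self, address: int, line: int, t: float, queue: EventQueue):
        """Route a pre-synaptic arrival into the neuron backend.

        Returns True when the neuron fires immediately; analog crossings that
        trail the arrival are scheduled on the queue as _FIRE events.
        """
        neurons = self.neurons
        if isinstance(neurons, dict):  # plain analog backend
            neuron = neurons.get(address)
            if neuron is None:
                neuron = neurons[address] = AnalogNeuron(self._analog_params)
            pending = neuron.on_presyn(t, line)
            if pending is not None:
                t_fire, pid = pending
                queue.push(t_fire, (_FIRE, address, pid))
            return False
        return neurons.on_presyn(address, line, t)

    def recall(
        self,
        pattern: Pattern,
        t0: float = 0.0,
        noise: list[SpikeEvent] | None = None,
        initiation: int | None = None,
        reset: bool = True,
    ) -> RecallResult:
        """Present a pattern's first spikes and run the event loop to quiescence.

        The first ``initiation`` spikes (default from the config) are
        injected as post-synaptic spikes at their stored relative times
        offset by ``t0``; optional noise events (absolute times) are merged
        as pre-synaptic arrivals.  The run stops when the queue drains, at
        ``t0 + duration + quiescence_slack * max_delay``, or when the
        emitted-spike count exceeds ``all_firing_factor`` times the expected
        count (the all-firing state).
        """
        cfg = self.config
        if reset:
            self.reset_neurons()
        k = cfg.initiation if initiation is None else initiation
        k = min(k, len(pattern))
        queue = EventQueue()
        rel = pattern.times - pattern.times[0]
        for i in range(k):
            queue.push(t0 + float(rel[i]), (_POST, int(pattern.neurons[i])))
        for ev in noise or []:
            if not ev.is_presynaptic:
                raise ValueError("noise events must carry a synapse line")
            queue.push(ev.time, (_PRE, ev.address, ev.line, -1, 0))

        expected = max(len(pattern) - k, 1)
        cap = cfg.all_firing_factor * expected
        t_end = t0 + pattern.duration + cfg.quiescence_slack * cfg.max_delay
        result = RecallResult(injected=k)
        axons = self.axons
        spikes = result.spikes
        multiplexed = isinstance(self.neurons, MultiplexedNeuronArray)
        drops0 = self.neurons.drops if multiplexed else 0

        while queue:
            t, payload = queue.pop()
            if t > t_end:
                break
            kind = payload[0]
            if kind == _POST:
                for te, out, line, m, gen in axons.on_postsyn_spike(payload[1], t):
                    queue.push(te, (_PRE, out, line, m, gen))
            elif kind == _PRE:
                _, addr, line, m, gen = payload
                if m >= 0 and not axons.emission_valid(m, gen):
                    continue
                if self._deliver(addr, line, t, queue):
                    spikes.append((t, addr))
                    if len(spikes) > cap:
                        result.all_firing = True
                        log.warning("all-firing state detected at t=%.1f ms", t)
                        break
                    queue.push(t, (_POST, addr))
            else:  # _FIRE (analog backend)
                _, addr, pid = payload
                neuron = self.neurons.get(addr)
                if neuron is not None and neuron.confirm_fire(t, pid):
                    spikes.append((t, addr))
                    if len(spikes) > cap:
                        result.all_firing = True
                        break
                    queue.push(t, (_POST, addr))
        if multiplexed:
            result.dropped = self.neurons.drops - drops0
        return result

    # -- persistence ---------------------------------------------------------

    def save_axons(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.axons.to_json())

    def load_axons(self, path) -> None:
        with open(path) as fh:
            self.axons = AxonArray.from_json(fh.read())


def train(
    config: NetworkConfig,
    patterns: list[Pattern],
    mode: str = "programming",
    presentations: int = 5,
) -> PolychronousNetwork:
    """Build and train a network on the given patterns (see
    :meth:`PolychronousNetwork.train_patterns`)."""
    net = PolychronousNetwork(config)
    return net.train_patterns(patterns, mode=mode, presentations=presentations)


def recall(
    network: PolychronousNetwork,
    pattern: Pattern,
    t0: float = 0.0,
    noise: list[SpikeEvent] | None = None,
    **kwargs,
) -> RecallResult:
    return network.recall(pattern, t0=t0, noise=noise, **kwargs)
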