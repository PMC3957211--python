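"""Axon modules: programmable/adaptable delay paths between neurons.

An axon module holds one input address, four output addresses and four delay
values.  During training, modules are consumed strictly in physical order:
each training spike configures the lowest unconfigured module's input
address, and becomes the next output address (with the observed inter-spike
interval as the programmed delay) of up to four earlier modules of the same
pattern.  A stored pattern of S spikes therefore consumes exactly S modules,
giving a capacity of floor(n_modules / S) patterns.

During recall, a post-synaptic spike whose address matches a module's input
restarts that module's ramp generator; each configured path emits a
pre-synaptic spike to its output address, on its own active line, when the
ramp exceeds the stored delay.

Delay adaptation (spike-timing-dependent delay plasticity) nudges a stored
delay toward zero pre/post timing difference with one of three strategies:
exact one-step correction, a fixed step per presentation, or a step
proportional to the error (default coefficient 0.5).

The imperfection model emulates the analog axon array: a relative Gaussian
error applied when a delay is programmed (~10 % of the target), a bounded
per-emission jitter that persists after adaptation (<= 0.3 ms), and an
optional probability of a spurious emission on a neighbouring path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ProgrammingError
from .events import Pattern

log = logging.getLogger(__name__)

__all__ = [
    "AdaptationPolicy",
    "ImperfectionModel",
    "AxonArray",
    "adapt_delay",
    "program_delay",
]

_MIN_DELAY = 1e-6  # ms; delays live in the half-open interval (0, max_delay]


@dataclass(frozen=True)
class AdaptationPolicy:
    """Delay-update strategy: ``exact``, ``fixed_step`` or ``proportional``."""

    strategy: str = "proportional"
    step: float = 0.1  # ms, fixed_step strategy
    coefficient: float = 0.5  # proportional strategy

    def __post_init__(self):
        if self.strategy not in ("exact", "fixed_step", "proportional"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 < self.coefficient <= 1:
            raise ValueError("coefficient must be in (0, 1]")


@dataclass(frozen=True)
class ImperfectionModel:
    """Analog axon imperfections, reproducible from ``seed``.

    ``sigma`` — relative std of the one-off programming error;
    ``residual`` — bound (ms) of the per-emission timing jitter that remains
    after adaptation (ramp-generator noise); ``spurious_p`` — probability of
    an extra emission on a neighbouring delay path per genuine emission.
    """

    sigma: float = 0.10
    residual: float = 0.3
    spurious_p: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.residual < 0 or not 0 <= self.spurious_p <= 1:
            raise ValueError("imperfection parameters must be non-negative")


def adapt_delay(
    delay: float,
    t_pre_arrival: float,
    t_post_fire: float,
    policy: AdaptationPolicy,
    max_delay: float = 100.0,
) -> float:
    """One STDDP update: move the delay toward zero pre/post difference.

    With error Delta = t_pre_arrival - t_post_fire (positive when the spike
    arrived late), the delay is decreased by Delta (exact), by a fixed step
    in the direction of Delta, or by ``coefficient * Delta``.  The result is
    clamped to (0, max_delay].
    """
    delta = t_pre_arrival - t_post_fire
    if policy.strategy == "exact":
        new = delay - delta
    elif policy.strategy == "fixed_step":
        new = delay - policy.step * float(np.sign(delta))
    else:
        new = delay - policy.coefficient * delta
    return float(min(max(new, _MIN_DELAY), max_delay))


def program_delay(
    array: "AxonArray",
    module: int,
    path: int,
    t_input: float,
    t_output_spike: float,
    imperfection: ImperfectionModel | None = None,
) -> float:
    """Store the observed interval on one delay path; returns the stored value.

    Digital programming stores the interval exactly; with an imperfection
    model the stored value is scaled by (1 + eps), eps ~ N(0, sigma).
    """
    target = t_output_spike - t_input
    if target <= 0:
        raise ProgrammingError(f"non-positive delay {target} requested")
    if target > array.max_delay:
        raise ProgrammingError(f"delay {target} exceeds ramp range {array.max_delay}")
    stored = target
    if imperfection is not None and imperfection.sigma > 0:
        stored *= 1.0 + array.rng.normal(0.0, imperfection.sigma)
        stored = min(max(stored, _MIN_DELAY), array.max_delay)
    stored = array._quantize(stored)
    array.delays[module, path] = stored
    return stored


class AxonArray:
    """A bank of axon modules with sequential training-time allocation."""

    N_PATHS = 4

    def __init__(
        self,
        n_modules: int,
        max_delay: float = 100.0,
        quantization: float | None = None,
        imperfection: ImperfectionModel | None = None,
        seed: int | None = None,
    ):
        if n_modules <= 0:
            raise ValueError("need at least one axon module")
        self.n_modules = n_modules
        self.max_delay = max_delay
        self.quantization = quantization
        self.imperfection = imperfection
        self.rng = np.random.default_rng(
            imperfection.seed if (seed is None and imperfection is not None) else seed
        )
        self.input_addr = np.full(n_modules, -1, dtype=np.int64)
        self.out_addr = np.full((n_modules, self.N_PATHS), -1, dtype=np.int64)
        self.delays = np.full((n_modules, self.N_PATHS), np.nan)
        self.n_out = np.zeros(n_modules, dtype=np.int64)
        self.ramp_generation = np.zeros(n_modules, dtype=np.int64)
        self.n_allocated = 0
        self.pattern_slices: list[tuple[int, int]] = []  # [start, end) per pattern
        self._open: list[int] = []  # modules of the current pattern with < 4 outputs
        self._input_time: dict[int, float] = {}
        self._index: dict[int, list[int]] | None = None

    # -- training-time allocation ------------------------------------------

    def begin_pattern(self) -> None:
        """Close the previous pattern: its trailing modules keep < 4 outputs."""
        self._open.clear()
        self._input_time.clear()
        self.pattern_slices.append((self.n_allocated, self.n_allocated))

    def on_training_spike(self, t: float, address: int, *, program: bool = True) -> int:
        """Consume one training spike: extend open modules, allocate a new one.

        Every already-configured module of the current pattern with fewer
        than four outputs latches this spike's address as its next output and
        (when ``program``) stores the elapsed interval on that path.  Then
        the next module in physical order latches the address as its input.
        Returns the newly allocated module index.
        """
        still_open = []
        for m in self._open:
            j = int(self.n_out[m])
            self.out_addr[m, j] = address
            if program:
                program_delay(self, m, j, self._input_time[m], t, self.imperfection)
            self.n_out[m] = j + 1
            if j + 1 < self.N_PATHS:
                still_open.append(m)
        self._open = still_open

        if self.n_allocated >= self.n_modules:
            raise CapacityError(pattern_index=len(self.pattern_slices) - 1)
        m = self.n_allocated
        self.n_allocated += 1
        self.input_addr[m] = address
        self._input_time[m] = t
        self._open.append(m)
        start, _ = self.pattern_slices[-1]
        self.pattern_slices[-1] = (start, self.n_allocated)
        self._index = None
        return m

    def train_pattern(self, pattern: Pattern, *, program: bool = True) -> tuple[int, int]:
        """Allocate (and optionally delay-program) one pattern; returns its slice."""
        self.begin_pattern()
        for neuron, t in pattern.spikes():
            self.on_training_spike(t, int(neuron), program=program)
        return self.pattern_slices[-1]

    def randomize_delays(self, rng: np.random.Generator | None = None) -> None:
        """Random initial delays (uniform over (0, max_delay]) on configured paths."""
        rng = rng or self.rng
        for m in range(self.n_allocated):
            k = int(self.n_out[m])
            if k:
                self.delays[m, :k] = self._quantize(
                    rng.uniform(_MIN_DELAY, self.max_delay, k)
                )

    # -- recall-time emission ----------------------------------------------

    def _build_index(self) -> dict[int, list[int]]:
        index: dict[int, list[int]] = {}
        for m in range(self.n_allocated):
            index.setdefault(int(self.input_addr[m]), []).append(m)
        self._index = index
        return index

    def on_postsyn_spike(
        self, address: int, t: float
    ) -> list[tuple[float, int, int, int, int]]:
        """Restart the ramps of all modules listening to ``address``.

        Returns scheduled pre-synaptic emissions as tuples
        ``(time, output_address, line, module, ramp_generation)``.  Each path
        j emits at ``t + delays[j]`` on active line j.  Re-triggering a
        module increments its ramp generation, which cancels emissions still
        pending from the previous trigger (callers check the generation when
        the emission falls due).  The imperfection model adds per-emission
        jitter and, with probability ``spurious_p``, a spurious emission on a
        neighbouring path.
        """
        index = self._index if self._index is not None else self._build_index()
        mods = index.get(address)
        if not mods:
            return []
        out = []
        imp = self.imperfection
        for m in mods:
            self.ramp_generation[m] += 1
            gen = int(self.ramp_generation[m])
            k = int(self.n_out[m])
            for j in range(k):
                te = t + self.delays[m, j]
                if imp is not None:
                    if imp.residual > 0:
                        te += self.rng.uniform(-imp.residual, imp.residual)
                    if imp.spurious_p > 0 and self.rng.random() < imp.spurious_p:
                        nj = (j + (1 if self.rng.random() < 0.5 else -1)) % k
                        out.append(
                            (te, int(self.out_addr[m, nj]), int(nj), m, gen)
                        )
                out.append((max(te, t), int(self.out_addr[m, j]), j, m, gen))
        return out

    def emission_valid(self, module: int, generation: int) -> bool:
        return int(self.ramp_generation[module]) == generation

    # -- delay adaptation ---------------------------------------------------

    def adapt_on_replay(self, pattern_index: int, pattern: Pattern, policy: AdaptationPolicy) -> None:
        """One noiseless training presentation of a stored pattern.

        The pattern is presented externally, so every neuron fires at its
        stored time; each delay path's pre-synaptic arrival is paired with
        the fire of the neuron whose address it latched (position pairing:
        path j of the pattern's k-th module targets spike k+1+j), and the
        policy moves the delay toward zero timing difference.  With the
        imperfection model active each measured arrival carries the
        ramp-noise jitter, so adaptation converges only to within the
        residual bound.
        """
        start, end = self.pattern_slices[pattern_index]
        times = pattern.times
        if end - start != len(times):
            raise ValueError("pattern length does not match its stored slice")
        imp = self.imperfection
        for k in range(end - start):
            m = start + k
            t_in = times[k]
            for j in range(int(self.n_out[m])):
                t_target = times[k + 1 + j]
                arrival = t_in + self.delays[m, j]
                if imp is not None and imp.residual > 0:
                    arrival += self.rng.uniform(-imp.residual, imp.residual)
                self.delays[m, j] = self._quantize(
                    adapt_delay(
                        float(self.delays[m, j]), arrival, t_target, policy, self.max_delay
                    )
                )

    # -- misc ----------------------------------------------------------------

    def _quantize(self, d):
        if self.quantization:
            q = self.quantization
            return np.maximum(np.round(np.asarray(d) / q) * q, q) if np.ndim(d) else max(
                round(d / q) * q, q
            )
        return d

    @property
    def n_configured(self) -> int:
        return self.n_allocated

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "n_modules": self.n_modules,
            "max_delay": self.max_delay,
            "quantization": self.quantization,
            "pattern_slices": self.pattern_slices,
            "modules": [
                {
                    "index": m,
                    "input": int(self.input_addr[m]),
                    "outputs": self.out_addr[m, : int(self.n_out[m])].tolist(),
                    "delays": self.delays[m, : int(self.n_out[m])].tolist(),
                }
                for m in range(self.n_allocated)
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AxonArray":
        doc = json.loads(text)
        arr = cls(
            n_modules=doc["n_modules"],
            max_delay=doc["max_delay"],
            quantization=doc.get("quantization"),
        )
        for mod in doc["modules"]:
            m = mod["index"]
            arr.input_addr[m] = mod["input"]
            k = len(mod["outputs"])
            arr.out_addr[m, :k] = mod["outputs"]
            arr.delays[m, :k] = mod["delays"]
            arr.n_out[m] = k
            arr.n_allocated = max(arr.n_allocated, m + 1)
        arr.pattern_slices = [tuple(s) for s in doc.get("pattern_slices", [])]
        return arr
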