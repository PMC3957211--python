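"""Synthetic spatio-temporal patterns, Poisson noise, and recall scoring.

Patterns emulate the hardware pattern generator: spike addresses drawn
uniformly over the network (so stored patterns are evenly spread), with no
neuron repeated within any five consecutive spikes (a neuron never receives
a delayed spike from itself), and inter-spike intervals i.i.d. uniform in
5-15 ms — a 51-spike pattern thus spans about 500 ms, i.e. 50 events firing
at roughly 100 spikes per second.  Disjoint mode partitions the neuron
population across patterns for cross-talk-free measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PatternSpecError
from .events import Pattern, RecallResult, SpikeEvent

__all__ = [
    "PatternSpec",
    "NoiseSpec",
    "RecallMetrics",
    "generate_patterns",
    "generate_noise",
    "score_recall",
    "summarize",
]


@dataclass(frozen=True)
class PatternSpec:
    """Conditions for the random pattern generator."""

    n_patterns: int = 1
    n_spikes: int = 51
    n_neurons: int = 4096
    isi_low: float = 5.0  # ms
    isi_high: float = 15.0  # ms
    disjoint: bool = False
    no_repeat_window: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_patterns <= 0 or self.n_spikes <= 0 or self.n_neurons <= 0:
            raise PatternSpecError("counts must be positive")
        if not 0 < self.isi_low <= self.isi_high:
            raise PatternSpecError("ISI bounds must be positive and ordered")
        if self.disjoint and self.n_patterns * self.n_spikes > self.n_neurons:
            raise PatternSpecError(
                f"disjoint mode needs n_patterns*n_spikes <= n_neurons "
                f"({self.n_patterns}*{self.n_spikes} > {self.n_neurons})"
            )
        if not self.disjoint and self.n_neurons <= self.no_repeat_window:
            raise PatternSpecError("network too small for the no-repeat window")


@dataclass(frozen=True)
class NoiseSpec:
    """Homogeneous Poisson noise over the whole network.

    ``rate`` is the total number of extra spikes per second across the
    network (2-128 in the noise experiments), not a per-neuron rate; each
    event hits a uniformly random neuron on a uniformly random synapse line.
    """

    rate: float = 0.0  # spikes/s, whole network
    duration: float = 1000.0  # ms
    n_neurons: int = 4096
    n_lines: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0 or self.duration < 0:
            raise PatternSpecError("rate and duration must be non-negative")


def generate_patterns(spec: PatternSpec) -> list[Pattern]:
    """Draw random patterns; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    patterns = []
    if spec.disjoint:
        perm = rng.permutation(spec.n_neurons)
    for p in range(spec.n_patterns):
        if spec.disjoint:
            neurons = perm[p * spec.n_spikes : (p + 1) * spec.n_spikes]
        else:
            neurons = np.empty(spec.n_spikes, dtype=np.int64)
            window = spec.no_repeat_window - 1
            for i in range(spec.n_spikes):
                recent = set(neurons[max(0, i - window) : i].tolist())
                n = int(rng.integers(spec.n_neurons))
                while n in recent:
                    n = int(rng.integers(spec.n_neurons))
                neurons[i] = n
        isis = rng.uniform(spec.isi_low, spec.isi_high, spec.n_spikes - 1)
        times = np.concatenate([[0.0], np.cumsum(isis)])
        patterns.append(Pattern(neurons=np.asarray(neurons, dtype=np.int64), times=times))
    return patterns


def generate_noise(spec: NoiseSpec) -> list[SpikeEvent]:
    """Poisson spike noise: count ~ Poisson(rate * duration), times uniform."""
    rng = np.random.default_rng(spec.seed)
    n = rng.poisson(spec.rate * spec.duration / 1000.0)
    times = np.sort(rng.uniform(0.0, spec.duration, n))
    neurons = rng.integers(0, spec.n_neurons, n)
    lines = rng.integers(0, spec.n_lines, n)
    return [
        SpikeEvent(float(t), int(a), int(l)) for t, a, l in zip(times, neurons, lines)
    ]


@dataclass
class RecallMetrics:
    """Per-pattern recall score."""

    fraction: float
    matched: int
    expected: int
    success: bool
    all_firing: bool = False


def score_recall(
    expected: Pattern,
    emitted: list[tuple[float, int]] | RecallResult,
    t0: float = 0.0,
    tolerance: float = 1.0,
    success_threshold: float = 0.95,
    n_initiation: int = 3,
    all_firing: bool | None = None,
) -> RecallMetrics:
    """Score one recall run against the stored pattern.

    A stored spike (n, t) counts as recalled iff an emitted spike of neuron
    ``n`` lies within ``tolerance`` ms of ``t0 + t`` (greedy one-to-one
    matching in time order).  The injected initiation spikes are excluded
    from the denominator.  A pattern is successfully recalled when the
    recalled fraction reaches ``success_threshold`` and the run did not end
    in the all-firing state.
    """
    if isinstance(emitted, RecallResult):
        if all_firing is None:
            all_firing = emitted.all_firing
        emitted = emitted.spikes
    all_firing = bool(all_firing)

    by_neuron: dict[int, list[float]] = {}
    for t, n in sorted(emitted):
        by_neuron.setdefault(n, []).append(t)
    used: dict[int, int] = {n: 0 for n in by_neuron}

    rel = expected.times - expected.times[0]
    matched = 0
    denominator = 0
    for i in range(n_initiation, len(expected)):
        denominator += 1
        n = int(expected.neurons[i])
        target = t0 + float(rel[i])
        times = by_neuron.get(n)
        if not times:
            continue
        j = used[n]
        while j < len(times) and times[j] < target - tolerance:
            j += 1
        used[n] = j
        if j < len(times) and abs(times[j] - target) <= tolerance:
            matched += 1
            used[n] = j + 1
    fraction = matched / denominator if denominator else 1.0
    success = fraction >= success_threshold and not all_firing
    return RecallMetrics(
        fraction=fraction,
        matched=matched,
        expected=denominator,
        success=success,
        all_firing=all_firing,
    )


def summarize(metrics: list[RecallMetrics]) -> dict:
    """Aggregate per-pattern metrics into the standard report."""
    if not metrics:
        return {
            "n_patterns": 0,
            "percent_patterns_recalled": float("nan"),
            "mean_percent_spikes_recalled": float("nan"),
            "any_all_firing": False,
        }
    return {
        "n_patterns": len(metrics),
        "percent_patterns_recalled": 100.0 * np.mean([m.success for m in metrics]),
        "mean_percent_spikes_recalled": 100.0 * np.mean([m.fraction for m in metrics]),
        "any_all_firing": any(m.all_firing for m in metrics),
    }


def metrics_to_frame(metrics: list[RecallMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fraction": [m.fraction for m in metrics],
            "matched": [m.matched for m in metrics],
            "expected": [m.expected for m in metrics],
            "success": [m.success for m in metrics],
            "all_firing": [m.all_firing for m in metrics],
        }
    )
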