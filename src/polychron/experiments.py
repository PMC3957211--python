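"""Reference experiments: size sweep, noise sweep, capacity, analog emulation.

Each runner regenerates its inputs from a seed, trains a fresh network,
recalls every stored pattern and returns a tidy DataFrame, so all reported
numbers are recomputed from scratch on every call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .aer import (
    NEURON_BUS,
    SkewGlitchModel,
    build_codebook,
    sample_bus,
    synthesize_bus_waveform,
)
from .axons import AdaptationPolicy, ImperfectionModel
from .events import SpikeEvent
from .network import NetworkConfig, PolychronousNetwork
from .patterns import (
    NoiseSpec,
    PatternSpec,
    generate_noise,
    generate_patterns,
    score_recall,
    summarize,
)

log = logging.getLogger(__name__)

__all__ = [
    "run_recall_suite",
    "size_sweep",
    "noise_sweep",
    "capacity_experiment",
    "analog_axon_experiment",
    "interface_experiment",
]


def run_recall_suite(
    network: PolychronousNetwork,
    patterns,
    tolerance: float = 1.0,
    success_threshold: float = 0.95,
    noise: list[SpikeEvent] | None = None,
) -> pd.DataFrame:
    """Recall every pattern once and score it; one row per pattern."""
    rows = []
    k = network.config.initiation
    for i, pattern in enumerate(patterns):
        result = network.recall(pattern, noise=noise)
        m = score_recall(
            pattern,
            result,
            tolerance=tolerance,
            success_threshold=success_threshold,
            n_initiation=min(k, len(pattern)),
        )
        rows.append(
            {
                "pattern": i,
                "fraction": m.fraction,
                "success": m.success,
                "all_firing": m.all_firing,
                "dropped": result.dropped,
            }
        )
    return pd.DataFrame(rows)


def _seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def size_sweep(
    sizes=(128, 256, 512, 1024),
    n_patterns: int = 82,
    n_spikes: int = 51,
    runs: int = 10,
    base_seed: int = 0,
    max_recalls: int | None = None,
    backend: str = "digital",
    mode: str = "programming",
) -> pd.DataFrame:
    """Recall performance vs neuron-array size at full axon-array load.

    Defaults reproduce the 82-patterns-of-51-spikes load (one pattern per
    ~51 axon modules); small arrays collapse into the all-firing state,
    larger ones approach perfect recall.  ``max_recalls`` limits how many of
    the stored patterns are recalled per run (useful for the all-firing
    sizes, where every recall explodes and is stopped early).
    """
    rows = []
    for size in sizes:
        for run, seed in enumerate(_seeds(base_seed, runs)):
            spec = PatternSpec(
                n_patterns=n_patterns, n_spikes=n_spikes, n_neurons=size, seed=seed
            )
            patterns = generate_patterns(spec)
            config = NetworkConfig(
                n_neurons=size,
                n_axon_modules=n_patterns * n_spikes,
                backend=backend,
                seed=seed,
            )
            net = PolychronousNetwork(config).train_patterns(patterns, mode=mode)
            subset = patterns[: max_recalls or len(patterns)]
            frame = run_recall_suite(net, subset)
            agg = summarize_frame(frame)
            rows.append({"n_neurons": size, "run": run, **agg})
    return pd.DataFrame(rows)


def summarize_frame(frame: pd.DataFrame) -> dict:
    return {
        "percent_patterns_recalled": 100.0 * frame["success"].mean(),
        "mean_percent_spikes_recalled": 100.0 * frame["fraction"].mean(),
        "any_all_firing": bool(frame["all_firing"].any()),
        "percent_all_firing": 100.0 * frame["all_firing"].mean(),
    }


def noise_sweep(
    rates=(2, 4, 8, 16, 32, 64, 128),
    n_neurons: int = 4096,
    n_patterns: int = 82,
    n_spikes: int = 51,
    runs: int = 3,
    base_seed: int = 0,
    mode: str = "programming",
    max_recalls: int | None = None,
) -> pd.DataFrame:
    """Recall robustness against network-wide Poisson noise (2-128 spikes/s).

    Noise is injected during recall only — the first training presentation
    is always clean.
    """
    rows = []
    for rate in rates:
        for run, seed in enumerate(_seeds(base_seed, runs)):
            spec = PatternSpec(
                n_patterns=n_patterns, n_spikes=n_spikes, n_neurons=n_neurons, seed=seed
            )
            patterns = generate_patterns(spec)
            config = NetworkConfig(
                n_neurons=n_neurons, n_axon_modules=n_patterns * n_spikes, seed=seed
            )
            net = PolychronousNetwork(config).train_patterns(patterns, mode=mode)
            scores = []
            subset = patterns[: max_recalls or len(patterns)]
            for i, pattern in enumerate(subset):
                noise = generate_noise(
                    NoiseSpec(
                        rate=rate,
                        duration=pattern.duration + 50.0,
                        n_neurons=n_neurons,
                        seed=seed + 7919 * i,
                    )
                )
                result = net.recall(pattern, noise=noise)
                scores.append(
                    score_recall(pattern, result, n_initiation=net.config.initiation)
                )
            agg = summarize(scores)
            rows.append({"rate": rate, "run": run, **agg})
    return pd.DataFrame(rows)


def capacity_experiment(
    n_patterns: int = 1200,
    n_neurons: int = 4096,
    n_modules: int = 81920,
    n_spikes: int = 51,
    runs: int = 3,
    base_seed: int = 0,
    mode: str = "programming",
) -> pd.DataFrame:
    """Storage capacity at scale: 4k neurons, 80k axon modules."""
    rows = []
    for run, seed in enumerate(_seeds(base_seed, runs)):
        spec = PatternSpec(
            n_patterns=n_patterns, n_spikes=n_spikes, n_neurons=n_neurons, seed=seed
        )
        patterns = generate_patterns(spec)
        config = NetworkConfig(n_neurons=n_neurons, n_axon_modules=n_modules, seed=seed)
        net = PolychronousNetwork(config).train_patterns(patterns, mode=mode)
        frame = run_recall_suite(net, patterns)
        rows.append({"run": run, "n_patterns": n_patterns, **summarize_frame(frame)})
    return pd.DataFrame(rows)


def analog_axon_experiment(
    lengths=(20, 25, 33, 50),
    n_modules: int = 100,
    n_neurons: int = 126,
    runs: int = 20,
    base_seed: int = 0,
    sigma: float = 0.10,
    residual: float = 0.3,
    adapt_iterations: int = 20,
    adapt_step: float = 0.1,
) -> pd.DataFrame:
    """Analog axon array emulation: per-pattern spike-recall fractions.

    Disjoint (zero-overlap) patterns on a 126-neuron digital coincidence
    array behind a 100-module axon array with the analog imperfection model.
    For each pattern length the array is filled to capacity
    (floor(100/length) patterns), once with delay programming alone and once
    followed by fixed-step delay adaptation.
    """
    rows = []
    for length in lengths:
        n_patterns = n_modules // length
        for run, seed in enumerate(_seeds(base_seed, runs)):
            spec = PatternSpec(
                n_patterns=n_patterns,
                n_spikes=length,
                n_neurons=n_neurons,
                disjoint=True,
                seed=seed,
            )
            patterns = generate_patterns(spec)
            for adapted in (False, True):
                config = NetworkConfig(
                    n_neurons=n_neurons,
                    n_axon_modules=n_modules,
                    imperfection=ImperfectionModel(
                        sigma=sigma, residual=residual, seed=seed
                    ),
                    seed=seed,
                )
                net = PolychronousNetwork(config).train_patterns(patterns)
                if adapted:
                    net.adapt(
                        adapt_iterations,
                        AdaptationPolicy(strategy="fixed_step", step=adapt_step),
                    )
                frame = run_recall_suite(net, patterns)
                for _, row in frame.iterrows():
                    rows.append(
                        {
                            "length": length,
                            "run": run,
                            "pattern": int(row["pattern"]),
                            "adapted": adapted,
                            "fraction": row["fraction"],
                        }
                    )
    return pd.DataFrame(rows)


def interface_experiment(
    n_addresses: int = 50,
    repetitions: int = 128,
    runs: int = 10,
    base_seed: int = 0,
    interval: float = 5.0,  # microseconds between spikes on the bus
    pulse_width: float = 1.0,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Stress the synchroniser: every address sent repeatedly through a
    skewed, glitchy bus; counts correct single samples, immediate duplicates
    and wrong addresses per run."""
    book = build_codebook(NEURON_BUS)
    rows = []
    for run, seed in enumerate(_seeds(base_seed, runs)):
        model = SkewGlitchModel(seed=seed, **(model_kwargs or {}))
        events = [
            SpikeEvent(time=interval * (1 + i), address=i % n_addresses, line=0)
            for i in range(n_addresses * repetitions)
        ]
        wave = synthesize_bus_waveform(events, book, pulse_width, model)
        sampled = sample_bus(wave, book, n_active_lines=1)
        sent = [e.address for e in events]
        got = [s.address for s in sampled]
        # walk the sampled stream against the transmitted one: a repeat of the
        # immediately preceding address is a (benign) duplicate, anything that
        # does not line up with the next transmitted address is wrong
        duplicates = wrong = 0
        ptr = 0
        for a in got:
            if ptr < len(sent) and a == sent[ptr]:
                ptr += 1
            elif ptr > 0 and a == sent[ptr - 1]:
                duplicates += 1
            else:
                wrong += 1
        missed = len(sent) - ptr
        wrong += missed
        rows.append(
            {
                "run": run,
                "sent": len(sent),
                "sampled": len(got),
                "duplicates": duplicates,
                "wrong": wrong,
            }
        )
    return pd.DataFrame(rows)
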