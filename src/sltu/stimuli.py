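"""Stimulus generation: Boolean inputs as spike trains.

Two encodings of a Boolean 1 are supported:

* *rate interpretation* — the input fires a 100 Hz train: 25 spikes placed in
  25 distinct 1-ms bins sampled uniformly from a 250 ms window (spikes at bin
  starts);
* *spike interpretation* — time is divided into 25 ms bins; an active input
  emits one spike at the bin start plus a uniform ±1 ms jitter, clipped so it
  stays inside its bin.  Inputs active in the same bin therefore spike
  (near-)coincidentally.

Reproducibility contract: every train is drawn from a named substream keyed
by (master seed, context, input index), so adding or removing one input never
perturbs the spike times of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RATE_WINDOW_MS",
    "RATE_BIN_MS",
    "RATE_ACTIVE_BINS",
    "SPIKE_BIN_MS",
    "SPIKE_JITTER_MS",
    "StimulusProtocol",
    "substream",
    "gen_rate_train",
    "gen_coincident_spikes",
]

RATE_WINDOW_MS = 250.0
RATE_BIN_MS = 1.0
RATE_ACTIVE_BINS = 25  # 25 spikes / 250 ms = 100 Hz
SPIKE_BIN_MS = 25.0
SPIKE_JITTER_MS = 1.0


def substream(seed: int, *context: int) -> np.random.Generator:
    """Named substream: an independent generator keyed by seed and context."""
    return np.random.default_rng([int(seed)] + [int(c) for c in context])


def gen_rate_train(active: bool, seed: int, *context: int) -> list[float]:
    """100 Hz rate-coded train for one input (empty if the input is 0)."""
    if not active:
        return []
    rng = substream(seed, *context)
    n_bins = int(round(RATE_WINDOW_MS / RATE_BIN_MS))
    bins = rng.choice(n_bins, size=RATE_ACTIVE_BINS, replace=False)
    return sorted(float(b) * RATE_BIN_MS for b in bins)


def gen_coincident_spikes(
    pattern_bits: np.ndarray, seed: int, *context: int
) -> list[list[float]]:
    """Jittered coincident spikes from a (n_bins × n_inputs) activation matrix.

    Returns one spike-time list per input.  Each active (bin, input) pair
    contributes one spike at ``bin_start + U(−1, 1) ms``, clipped at the bin
    start so the spike stays in its bin.
    """
    bits = np.asarray(pattern_bits, dtype=int)
    if bits.ndim != 2:
        raise ValueError(f"pattern must be 2-D (bins × inputs), got shape {bits.shape}")
    n_bins, n_inputs = bits.shape
    trains: list[list[float]] = []
    for i in range(n_inputs):
        rng = substream(seed, *context, i)
        train = []
        for b in range(n_bins):
            jitter = rng.uniform(-SPIKE_JITTER_MS, SPIKE_JITTER_MS)
            if bits[b, i]:
                train.append(b * SPIKE_BIN_MS + max(0.0, jitter))
        trains.append(train)
    return trains


@dataclass(frozen=True)
class StimulusProtocol:
    """Per-input spike trains plus the metadata needed to read the output back.

    ``interpretation`` is one of ``rate``, ``spike`` or ``single_shot``; the
    spike trains are already resolved to times (ms) within ``[0, T_ms)``.
    """

    interpretation: str
    trains_ms: tuple[tuple[float, ...], ...]
    T_ms: float
    seed: int | None = None
    bin_ms: float = field(default=SPIKE_BIN_MS)

    def __post_init__(self) -> None:
        if self.interpretation not in ("rate", "spike", "single_shot"):
            raise ValueError(f"unknown interpretation {self.interpretation!r}")
        trains = tuple(tuple(float(t) for t in tr) for tr in self.trains_ms)
        object.__setattr__(self, "trains_ms", trains)
        for tr in trains:
            if any(not 0 <= t < self.T_ms for t in tr):
                raise ValueError(f"spike time outside [0, {self.T_ms}) ms")

    @classmethod
    def rate(cls, pattern: tuple[int, ...], seed: int, *context: int) -> "StimulusProtocol":
        """Rate-coded trains for one Boolean input pattern."""
        trains = tuple(
            tuple(gen_rate_train(bool(b), seed, *context, i))
            for i, b in enumerate(pattern)
        )
        return cls("rate", trains, RATE_WINDOW_MS, seed)

    @classmethod
    def spike(cls, pattern_bits: np.ndarray, seed: int, *context: int) -> "StimulusProtocol":
        """Jittered coincident spikes for a (bins × inputs) activation matrix."""
        bits = np.asarray(pattern_bits, dtype=int)
        trains = tuple(tuple(tr) for tr in gen_coincident_spikes(bits, seed, *context))
        return cls("spike", trains, bits.shape[0] * SPIKE_BIN_MS, seed)

    @classmethod
    def single_shot(cls, n_inputs: int, t_ms: float, T_ms: float) -> "StimulusProtocol":
        """All inputs fire exactly once, simultaneously at ``t_ms``."""
        return cls("single_shot", tuple((t_ms,) for _ in range(n_inputs)), T_ms)
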