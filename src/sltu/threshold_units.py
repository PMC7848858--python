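"""Binary neuron models: the linear and the sub-linear threshold unit.

An LTU (perceptron-style point neuron) fires when the weighted input sum
reaches its threshold.  An SLTU routes binary synapses onto ``d`` dendritic
subunits; each subunit saturates (clips its sum at 1, the ``E`` function)
before the subunit outputs are summed and thresholded at the soma.  The
saturating stage models the loss of synaptic driving force when co-located
inputs depolarise a thin dendrite together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boolean import BooleanFunction, truth_table

__all__ = ["LTUConfig", "SLTUConfig", "eval_ltu", "eval_sltu"]


@dataclass(frozen=True)
class LTUConfig:
    """Point-neuron threshold unit: ``f(X) = [Σ w_i X_i ≥ Θ]``.

    Weights are non-negative integers (finite synaptic resolution); the
    threshold is a positive integer.
    """

    weights: tuple[int, ...]
    theta: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(int(w) for w in self.weights))
        if any(w < 0 for w in self.weights):
            raise ValueError(f"weights must be non-negative, got {self.weights}")
        if self.theta < 1:
            raise ValueError(f"threshold must be >= 1, got {self.theta}")

    @property
    def n(self) -> int:
        return len(self.weights)

    def truth_table(self) -> BooleanFunction:
        return truth_table(lambda x: eval_ltu(self, x), self.n)


@dataclass(frozen=True)
class SLTUConfig:
    """Two-layer unit with ``d`` saturating dendrites.

    ``weights[j][i]`` is 1 when input ``i`` makes a (binary) synapse on
    dendrite ``j``.  Each dendrite computes ``E(Σ_i w_ji X_i)`` with
    ``E(Y) = min(Y, 1)``; the soma fires when the dendritic outputs sum to at
    least ``Θ``.  An input's total synaptic weight is its number of contacts,
    ``Σ_j w_ji``.
    """

    weights: tuple[tuple[int, ...], ...]  # shape (d, n), binary
    theta: int

    def __post_init__(self) -> None:
        w = tuple(tuple(int(v) for v in row) for row in self.weights)
        object.__setattr__(self, "weights", w)
        if not w:
            raise ValueError("need at least one dendrite")
        widths = {len(row) for row in w}
        if len(widths) != 1:
            raise ValueError(f"ragged weight matrix, row lengths {sorted(widths)}")
        if any(v not in (0, 1) for row in w for v in row):
            raise ValueError("SLTU weights are binary (0/1 placement matrix)")
        if self.theta < 1:
            raise ValueError(f"threshold must be >= 1, got {self.theta}")

    @property
    def d(self) -> int:
        return len(self.weights)

    @property
    def n(self) -> int:
        return len(self.weights[0])

    def total_weights(self) -> tuple[int, ...]:
        """Per-input number of synaptic contacts, ``w_i = Σ_j w_ji``."""
        return tuple(int(s) for s in np.asarray(self.weights).sum(axis=0))

    def truth_table(self) -> BooleanFunction:
        return truth_table(lambda x: eval_sltu(self, x), self.n)


def _check_len(x: Sequence[int], n: int) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    if x.shape != (n,):
        raise ValueError(f"input has length {x.shape[0] if x.ndim else 0}, unit takes {n}")
    return x


def eval_ltu(config: LTUConfig, x: Sequence[int]) -> int:
    """1 iff the weighted input sum reaches the threshold."""
    x = _check_len(x, config.n)
    return int(np.dot(config.weights, x) >= config.theta)


def eval_sltu(config: SLTUConfig, x: Sequence[int]) -> int:
    """1 iff the saturated dendritic sums reach the somatic threshold."""
    x = _check_len(x, config.n)
    dendritic = np.minimum(np.asarray(config.weights) @ x, 1)
    return int(dendritic.sum() >= config.theta)
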