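"""Minimal integer synaptic-weight analysis.

How much synaptic *resolution* — the size of the largest integer weight —
does a point neuron need for a computation, and how much does a neuron with
saturating dendrites need?  For the dominant-AND family the answers diverge:
an LTU needs a dominant weight ``n − 1`` times the smallest weight (so the
required resolution grows linearly with the number of inputs), while a
two-dendrite SLTU implements every ``n`` with unit weights and a fixed
threshold of 2.

The exhaustive solver below certifies minimality directly for small ``n``;
the analytic path handles the dominant-AND for arbitrary ``n`` using the two
binding constraints of the lower-bound argument, so no 2^n enumeration is
ever needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .boolean import (
    BooleanFunction,
    dand,
    input_vectors,
    is_linearly_separable,
    is_positive,
    truth_table,
)
from .threshold_units import LTUConfig, SLTUConfig

__all__ = [
    "MinimalRealization",
    "FunctionClass",
    "min_ltu_realization",
    "min_dand_dominant_weight",
    "sltu_dand_construction",
    "enumerate_positive_threshold_classes",
    "verify_dand_resolution_law",
]

#: exhaustive-search ceiling; beyond this the solver space explodes
MAX_EXHAUSTIVE_INPUTS = 4


@dataclass(frozen=True)
class MinimalRealization:
    """An LTU (or SLTU) realization certified minimal by exhaustive search.

    ``objective`` is the lexicographic value (max weight, sum of weights, Θ)
    the solver minimized: the leading term is the synaptic resolution.
    """

    config: LTUConfig | SLTUConfig
    objective: tuple[int, int, int]


@dataclass(frozen=True)
class FunctionClass:
    """A permutation orbit of Boolean functions with a canonical representative.

    The representative is the lexicographically smallest table in the orbit,
    which places the dominant input (when there is one) at ``X_1``.
    """

    representative: BooleanFunction
    orbit: frozenset[str]  # bit strings
    name: str | None = None

    @property
    def size(self) -> int:
        return len(self.orbit)


def min_ltu_realization(f: BooleanFunction) -> MinimalRealization:
    """Exhaustively minimal non-negative-integer LTU for ``f``.

    Scans all weight vectors with entries in ``[0, 2^n]`` (ample for these
    functions; minimality is certified by the scan itself), picks for each the
    least feasible integer threshold, and minimizes (max w, Σw, Θ)
    lexicographically, breaking remaining ties by the smallest weight vector.
    """
    n = f.n
    if n > MAX_EXHAUSTIVE_INPUTS:
        raise ValueError(f"exhaustive search limited to n <= {MAX_EXHAUSTIVE_INPUTS}, got {n}")
    if not is_positive(f):
        raise ValueError("function is not positive: no non-negative-weight LTU exists")
    if not is_linearly_separable(f):
        raise ValueError("function is not linearly separable: no LTU realizes it")
    if f.table[0] == 1:
        raise ValueError("f(0,...,0)=1 cannot be realized with a threshold >= 1")

    X = input_vectors(n).astype(np.int64)
    y = np.asarray(f.table, dtype=bool)
    bound = 2**n
    grid = np.array(list(itertools.product(range(bound + 1), repeat=n)), dtype=np.int64)
    sums = grid @ X.T  # (n_vectors, 2^n)
    ones_min = sums[:, y].min(axis=1)
    zeros_max = sums[:, ~y].max(axis=1)
    feasible = ones_min >= zeros_max + 1
    if not feasible.any():
        raise RuntimeError("no realization within the weight bound — should not happen")
    gw = grid[feasible]
    theta = zeros_max[feasible] + 1  # least threshold for each feasible vector
    keys = list(
        zip(
            gw.max(axis=1).tolist(),
            gw.sum(axis=1).tolist(),
            theta.tolist(),
            map(tuple, gw.tolist()),
        )
    )
    best = min(range(len(keys)), key=keys.__getitem__)
    w = tuple(int(v) for v in gw[best])
    cfg = LTUConfig(weights=w, theta=int(theta[best]))
    return MinimalRealization(config=cfg, objective=(max(w), sum(w), cfg.theta))


def min_dand_dominant_weight(n: int) -> tuple[int, int, int]:
    """Minimal LTU resolution for the dominant-AND of ``n`` inputs.

    Returns ``(w_1, w_min, Θ) = (n − 1, 1, n)`` after checking the two binding
    constraints that certify both feasibility and the lower bound:

    * silence without the dominant input: ``w_2 + ... + w_n < Θ``;
    * firing with the dominant input plus the weakest other:
      ``w_1 + w_min ≥ Θ``.

    Together they force ``Θ ≥ n·w_min`` and ``w_1 ≥ (n − 1)·w_min``, which the
    returned configuration meets with equality.
    """
    if n < 2:
        raise ValueError(f"dominant-AND needs n >= 2 inputs, got {n}")
    w1, wmin, theta = n - 1, 1, n
    # feasibility certificate (the proof's two extreme input patterns)
    if not (n - 1) * wmin < theta:
        raise AssertionError("silence constraint violated")
    if not w1 + wmin >= theta:
        raise AssertionError("firing constraint violated")
    return w1, wmin, theta


def sltu_dand_construction(n: int) -> SLTUConfig:
    """Two-dendrite, unit-weight SLTU implementing the dominant-AND of ``n``.

    Inputs 2..n share dendrite 1 (their joint contribution saturates at 1);
    the dominant input contacts dendrite 2 alone.  With Θ = 2 the soma needs
    both dendrites active, i.e. ``X_1`` AND at least one of the others.
    Weights and threshold are independent of ``n``.
    """
    if n < 2:
        raise ValueError(f"dominant-AND needs n >= 2 inputs, got {n}")
    shared = tuple([0] + [1] * (n - 1))
    alone = tuple([1] + [0] * (n - 1))
    return SLTUConfig(weights=(shared, alone), theta=2)


def _permute_table(bits: tuple[int, ...], perm: tuple[int, ...], n: int) -> tuple[int, ...]:
    """Table of f∘σ where σ permutes the inputs: g(X) = f(X_perm)."""
    out = [0] * len(bits)
    for k in range(len(bits)):
        x = [(k >> (n - 1 - i)) & 1 for i in range(n)]
        xp = [x[p] for p in perm]
        kp = 0
        for b in xp:
            kp = (kp << 1) | b
        out[k] = bits[kp]
    return tuple(out)


_N3_NAMES = {
    "01111111": "OR",
    "00010111": "AND/OR",
    "00000001": "AND",
    "00011111": "D-OR",
    "00000111": "D-AND",
}


def enumerate_positive_threshold_classes(n: int) -> list[FunctionClass]:
    """All permutation classes of positive threshold functions of exactly ``n`` inputs.

    Keeps the non-constant, linearly separable, positive functions that depend
    on every input, partitions them into orbits under input permutation, and
    returns class representatives sorted by their number of ones.  For n = 3
    the five classes carry their conventional names (OR, AND/OR, AND, D-OR,
    D-AND).
    """
    if n > MAX_EXHAUSTIVE_INPUTS:
        raise ValueError(f"enumeration limited to n <= {MAX_EXHAUSTIVE_INPUTS}, got {n}")
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")

    survivors: list[tuple[int, ...]] = []
    for code in range(2 ** (2**n)):
        bits = tuple((code >> k) & 1 for k in range(2**n - 1, -1, -1))
        f = BooleanFunction(n, bits)
        if len(set(bits)) == 1:  # constant
            continue
        if not is_positive(f):
            continue
        if not _depends_on_all(bits, n):
            continue
        if not is_linearly_separable(f):
            continue
        survivors.append(bits)

    perms = list(itertools.permutations(range(n)))
    seen: set[tuple[int, ...]] = set()
    classes: list[FunctionClass] = []
    for bits in survivors:
        if bits in seen:
            continue
        orbit = {_permute_table(bits, p, n) for p in perms}
        seen |= orbit
        rep_bits = min(orbit)
        rep = BooleanFunction(n, rep_bits)
        name = _N3_NAMES.get(rep.bits) if n == 3 else None
        if n == 2:
            name = {"0001": "AND", "0111": "OR"}.get(rep.bits)
        if n == 1:
            name = "identity" if rep.bits == "01" else None
        classes.append(
            FunctionClass(
                representative=rep,
                orbit=frozenset("".join(map(str, b)) for b in orbit),
                name=name,
            )
        )
    classes.sort(key=lambda c: (sum(c.representative.table), c.representative.bits))
    return classes


def _depends_on_all(bits: tuple[int, ...], n: int) -> bool:
    for i in range(n):
        mask = 1 << (n - 1 - i)
        if all(bits[k] == bits[k | mask] for k in range(2**n) if not k & mask):
            return False  # output never changes with input i
    return True


def verify_dand_resolution_law(n_max: int) -> dict[int, dict]:
    """Confirm the dominant-AND resolution law on the exhaustive range.

    For each ``n`` in 2..n_max the exhaustive solver's minimal realization is
    checked against the analytic path: dominant/min weight ratio exactly
    ``n − 1`` and threshold ``n``.  Returns a per-``n`` report.
    """
    if n_max > MAX_EXHAUSTIVE_INPUTS:
        raise ValueError(f"exhaustive verification limited to n <= {MAX_EXHAUSTIVE_INPUTS}")
    report: dict[int, dict] = {}
    for n in range(2, n_max + 1):
        f = truth_table(dand(n), n)
        real = min_ltu_realization(f)
        w = real.config.weights
        wmin = min(v for v in w if v > 0)
        ratio = w[0] / wmin
        w1_a, wmin_a, theta_a = min_dand_dominant_weight(n)
        analytic_cfg = LTUConfig(weights=(w1_a,) + (wmin_a,) * (n - 1), theta=theta_a)
        report[n] = {
            "weights": w,
            "theta": real.config.theta,
            "ratio": ratio,
            "ratio_matches": ratio == n - 1,
            "theta_matches": real.config.theta == n,
            "analytic_feasible": analytic_cfg.truth_table() == f,
        }
    return report
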