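"""Boolean functions on binary input vectors, and their algebra.

A Boolean function of ``n`` variables maps {0,1}^n to {0,1}.  Throughout the
package truth tables are stored in row order of the integer encoding of the
input vector, with ``X_1`` as the most significant bit: for n=3 the rows are
000, 001, 010, 011, 100, 101, 110, 111.

Two structural properties matter for threshold units:

* *positivity* (monotonicity): flipping any input from 0 to 1 never turns the
  output off.  A neuron whose synaptic weights are all excitatory can only
  compute positive functions.
* *linear separability*: some real weight vector ``w`` and threshold ``Θ``
  realize the function as ``f(X) = [w·X ≥ Θ]``.

The dominant-AND (``dand``) and dominant-OR (``dor``) families single out one
input (by convention ``X_1``) that is necessary, respectively sufficient, for
the output.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "BooleanFunction",
    "dand",
    "dor",
    "truth_table",
    "is_positive",
    "is_linearly_separable",
    "dual",
    "input_vectors",
]

#: refuse LP separability checks beyond this many inputs (2^n constraints)
MAX_SEPARABILITY_INPUTS = 20


def input_vectors(n: int) -> np.ndarray:
    """All 2^n binary input vectors as rows, X_1 in the leftmost column.

    Row ``k`` is the binary expansion of ``k``; this is the canonical row
    order used by every truth table in the package.
    """
    if n < 1:
        raise ValueError(f"need at least one input, got n={n}")
    ks = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return ((ks[:, None] >> shifts) & 1).astype(np.uint8)


@dataclass(frozen=True)
class BooleanFunction:
    """A truth table over ``n`` binary inputs.

    Parameters
    ----------
    n:
        Number of inputs (positive).
    table:
        Sequence of 2^n bits, indexed by the integer encoding of the input
        vector (``X_1`` = most significant bit).
    """

    n: int
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one input, got n={self.n}")
        object.__setattr__(self, "table", tuple(int(b) for b in self.table))
        if len(self.table) != 2**self.n:
            raise ValueError(
                f"table has {len(self.table)} entries, expected 2^{self.n} = {2**self.n}"
            )
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("truth table entries must be 0 or 1")

    def __call__(self, x: Sequence[int]) -> int:
        if len(x) != self.n:
            raise ValueError(f"input has {len(x)} bits, function takes {self.n}")
        idx = 0
        for bit in x:
            idx = (idx << 1) | int(bit)
        return self.table[idx]

    @property
    def bits(self) -> str:
        """Table as a bit string, e.g. '00000111' for the 3-input D-AND."""
        return "".join(str(b) for b in self.table)

    @classmethod
    def from_bits(cls, bits: str) -> "BooleanFunction":
        n = int(np.log2(len(bits)))
        if 2**n != len(bits):
            raise ValueError(f"bit string length {len(bits)} is not a power of two")
        return cls(n, tuple(int(c) for c in bits))

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "table": self.bits})

    @classmethod
    def from_json(cls, text: str) -> "BooleanFunction":
        obj = json.loads(text)
        f = cls.from_bits(obj["table"])
        if f.n != obj["n"]:
            raise ValueError(f"declared n={obj['n']} but table encodes n={f.n}")
        return f

    def to_csv(self, path) -> None:
        """Write the truth table as CSV, one row per input vector."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"X{i + 1}" for i in range(self.n)] + ["f"])
            for row, out in zip(input_vectors(self.n), self.table):
                w.writerow(list(map(int, row)) + [out])


def dand(n: int, x: Sequence[int] | None = None):
    """Dominant AND: ``X_1 AND (X_2 OR ... OR X_n)``.

    With ``x`` given, evaluates on that input vector; otherwise returns the
    evaluator so ``truth_table(dand(n), n)`` works.
    """
    if n < 2:
        raise ValueError(f"dominant-AND needs n >= 2 inputs, got {n}")

    def f(x: Sequence[int]) -> int:
        if len(x) != n:
            raise ValueError(f"input has {len(x)} bits, function takes {n}")
        return int(bool(x[0]) and any(x[1:]))

    return f if x is None else f(x)


def dor(n: int, x: Sequence[int] | None = None):
    """Dominant OR: ``X_1 OR (X_2 AND ... AND X_n)`` — the dual of ``dand``."""
    if n < 2:
        raise ValueError(f"dominant-OR needs n >= 2 inputs, got {n}")

    def f(x: Sequence[int]) -> int:
        if len(x) != n:
            raise ValueError(f"input has {len(x)} bits, function takes {n}")
        return int(bool(x[0]) or all(x[1:]))

    return f if x is None else f(x)


def truth_table(f: Callable[[Sequence[int]], int], n: int) -> BooleanFunction:
    """Tabulate ``f`` on all 2^n inputs in canonical row order."""
    rows = input_vectors(n)
    return BooleanFunction(n, tuple(int(f(tuple(row))) for row in rows))


def is_positive(f: BooleanFunction) -> bool:
    """Exhaustive monotonicity check.

    Equivalent to checking every componentwise-ordered pair; it suffices to
    compare each input vector against its single-bit-lowered neighbours.
    """
    table = np.asarray(f.table, dtype=np.uint8)
    for k in range(2**f.n):
        for i in range(f.n):
            if k & (1 << i) and table[k] < table[k & ~(1 << i)]:
                return False
    return True


def is_linearly_separable(f: BooleanFunction) -> bool:
    """Decide linear separability by LP feasibility.

    Encodes ``w·X ≥ Θ`` for rows with output 1 and ``w·X ≤ Θ − 1`` for rows
    with output 0.  The unit margin is lossless: any real separating plane for
    a finite set of 0/1 points can be scaled to satisfy it.
    """
    if f.n > MAX_SEPARABILITY_INPUTS:
        raise ValueError(
            f"n={f.n} exceeds the separability limit of {MAX_SEPARABILITY_INPUTS} inputs"
        )
    X = input_vectors(f.n).astype(float)
    y = np.asarray(f.table, dtype=bool)
    # variables: w_1..w_n, theta; all free
    a_ub = []
    b_ub = []
    for row, out in zip(X, y):
        if out:  # w·x - theta >= 0  ->  -(w·x) + theta <= 0
            a_ub.append(np.append(-row, 1.0))
            b_ub.append(0.0)
        else:  # w·x - theta <= -1
            a_ub.append(np.append(row, -1.0))
            b_ub.append(-1.0)
    res = linprog(
        c=np.zeros(f.n + 1),
        A_ub=np.asarray(a_ub),
        b_ub=np.asarray(b_ub),
        bounds=[(None, None)] * (f.n + 1),
        method="highs",
    )
    return bool(res.success)


def dual(f: BooleanFunction) -> BooleanFunction:
    """Boolean dual: ``g(X) = 1 − f(1−X)`` (swap the roles of AND and OR)."""
    m = 2**f.n - 1
    return BooleanFunction(f.n, tuple(1 - f.table[m - k] for k in range(m + 1)))


def brute_force_separable(f: BooleanFunction, bound: int = 4) -> bool:
    """Integer-weight search oracle for separability (small n only).

    Scans all integer weight vectors in [-bound, bound]^n with thresholds in
    [-n*bound, n*bound].  Independent of the LP path; used for cross-checks.
    """
    X = input_vectors(f.n).astype(int)
    y = np.asarray(f.table, dtype=bool)
    for w in itertools.product(range(-bound, bound + 1), repeat=f.n):
        s = X @ np.asarray(w)
        lo = s[y].min() if y.any() else None
        hi = s[~y].max() if (~y).any() else None
        # need theta with  hi < theta <= lo
        if lo is None or hi is None or hi < lo:
            return True
    return False
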