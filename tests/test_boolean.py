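"""Boolean-function algebra: tables, duality, positivity, separability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sltu import (
    BooleanFunction,
    dand,
    dor,
    dual,
    input_vectors,
    is_linearly_separable,
    is_positive,
    truth_table,
)
from sltu.boolean import brute_force_separable

XOR2 = BooleanFunction(2, (0, 1, 1, 0))


@pytest.mark.parametrize(
    "fn, n, x, expected",
    [
        (dand, 3, (1, 0, 1), 1),
        (dand, 3, (1, 0, 0), 0),
        (dand, 3, (0, 1, 1), 0),
        (dand, 5, (0, 1, 1, 1, 1), 0),
        (dor, 3, (1, 0, 0), 1),
        (dor, 3, (0, 1, 1), 1),
        (dor, 3, (0, 0, 1), 0),
    ],
)
def test_dominant_family_pointwise(fn, n, x, expected):
    assert fn(n, x) == expected


@pytest.mark.parametrize("fn", [dand, dor])
def test_dominant_family_rejects_single_input(fn):
    with pytest.raises(ValueError):
        fn(1)


def test_truth_tables_in_canonical_row_order():
    assert truth_table(dand(3), 3).bits == "00000111"
    assert truth_table(dor(3), 3).bits == "00011111"
    assert truth_table(lambda x: 0, 3).bits == "00000000"


def test_table_length_and_entries_validated():
    with pytest.raises(ValueError):
        BooleanFunction(2, (0, 1, 1))
    with pytest.raises(ValueError):
        BooleanFunction(1, (0, 2))


def test_positivity():
    assert is_positive(truth_table(dand(3), 3))
    assert not is_positive(XOR2)
    assert is_positive(BooleanFunction(2, (0, 0, 0, 0)))
    assert is_positive(BooleanFunction(2, (1, 1, 1, 1)))


def test_separability_examples():
    assert is_linearly_separable(truth_table(dand(3), 3))
    assert not is_linearly_separable(XOR2)
    and3 = truth_table(lambda x: int(all(x)), 3)
    assert is_linearly_separable(and3)


def test_separability_input_limit():
    f = BooleanFunction(1, (0, 1))
    big = BooleanFunction(21, tuple([0] * 2**21))
    with pytest.raises(ValueError):
        is_linearly_separable(big)
    assert is_linearly_separable(f)


def test_lp_agrees_with_integer_brute_force_n2():
    """Exhaustive: all 16 two-input functions, LP vs integer-weight search."""
    for code in range(16):
        bits = tuple((code >> k) & 1 for k in range(3, -1, -1))
        f = BooleanFunction(2, bits)
        assert is_linearly_separable(f) == brute_force_separable(f, bound=4), bits


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=255))
def test_lp_agrees_with_integer_brute_force_n3(code):
    bits = tuple((code >> k) & 1 for k in range(7, -1, -1))
    f = BooleanFunction(3, bits)
    assert is_linearly_separable(f) == brute_force_separable(f, bound=4)


def test_dual_swaps_and_and_or():
    assert dual(truth_table(dand(3), 3)) == truth_table(dor(3), 3)
    or3 = truth_table(lambda x: int(any(x)), 3)
    and3 = truth_table(lambda x: int(all(x)), 3)
    assert dual(or3) == and3
    maj3 = truth_table(lambda x: int(sum(x) >= 2), 3)
    assert dual(maj3) == maj3  # majority is self-dual


def test_dual_is_an_involution_for_all_n2_functions():
    for code in range(16):
        bits = tuple((code >> k) & 1 for k in range(3, -1, -1))
        f = BooleanFunction(2, bits)
        assert dual(dual(f)) == f


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**8 - 1))
def test_dual_is_an_involution_n3(code):
    bits = tuple((code >> k) & 1 for k in range(7, -1, -1))
    f = BooleanFunction(3, bits)
    assert dual(dual(f)) == f


def test_json_round_trip_and_csv(tmp_path):
    f = truth_table(dand(3), 3)
    assert BooleanFunction.from_json(f.to_json()) == f
    path = tmp_path / "dand.csv"
    f.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "X1,X2,X3,f"
    assert lines[1] == "0,0,0,0"
    assert lines[-1] == "1,1,1,1"
    assert len(lines) == 9


def test_input_vectors_msb_convention():
    rows = input_vectors(3)
    assert rows[5].tolist() == [1, 0, 1]  # row index 5 = binary 101
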