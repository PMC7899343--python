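"""The six consensus algorithms against a brute-force oracle and invariants."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crowdcount import ALGORITHMS, aggregate, aggregate_all


def oracle(values, algorithm):
    """Independent sort-then-slice reference implementation."""
    s = sorted(float(x) for x in values)  # statistics.mean coerces to input type
    if len(s) > 2:
        if "[3:Max]" in algorithm:
            s = s[2:]
        elif "[1:Max-2]" in algorithm:
            s = s[:-2]
    stat = statistics.mean if algorithm.startswith("Mean") else statistics.median
    return float(stat(s))


@pytest.mark.parametrize(
    "counts, algorithm, expected",
    [
        ([0, 1, 2, 2, 3], "Median[3:Max]", 2.0),
        ([0, 0, 7, 8], "Mean[1:Max-2]", 0.0),
        ([0, 0, 7, 8], "Mean", 3.75),
        ([0, 0, 7, 8], "Mean[3:Max]", 7.5),
        ([5, 5, 5, 5, 5], "Mean", 5.0),
        ([5, 5, 5, 5, 5], "Median[1:Max-2]", 5.0),
        ([2, 4], "Median[3:Max]", 3.0),  # n <= 2: fall back to plain median
        ([1, 2, 3, 4], "Median", 2.5),  # even length: midpoint, no rounding
    ],
)
def test_frozen_examples(counts, algorithm, expected):
    assert aggregate(counts, algorithm) == expected


def test_rejects_bad_inputs():
    with pytest.raises(ValueError, match="empty"):
        aggregate([], "Mean")
    with pytest.raises(ValueError, match="Median\\[3:Max\\]"):
        aggregate([1, 2], "Trimmed-mode")


counts_vectors = st.lists(st.integers(0, 50), min_size=1, max_size=15)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(v=counts_vectors, algorithm=st.sampled_from(ALGORITHMS))
def test_matches_bruteforce_oracle(v, algorithm):
    assert aggregate(v, algorithm) == oracle(v, algorithm)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(v=st.lists(st.integers(0, 50), min_size=3, max_size=15))
def test_trim_direction_orders_the_statistics(v):
    """Dropping the two lowest cannot decrease, the two highest cannot
    increase, either statistic."""
    for fam in ("Mean", "Median"):
        hi = aggregate(v, f"{fam}[3:Max]")
        mid = aggregate(v, fam)
        lo = aggregate(v, f"{fam}[1:Max-2]")
        assert hi >= mid >= lo


@settings(max_examples=150, deadline=None, derandomize=True)
@given(v=counts_vectors, k=st.integers(-20, 20), algorithm=st.sampled_from(ALGORITHMS))
def test_translation_equivariance_and_bounds(v, k, algorithm):
    base = aggregate(v, algorithm)
    assert aggregate([x + k for x in v], algorithm) == pytest.approx(base + k)
    assert min(v) <= base <= max(v)


def _matrix(vectors):
    rows = [
        ("f1", tile, sp, f"v{j}", c)
        for (tile, sp), vec in vectors.items()
        for j, c in enumerate(vec)
    ]
    return pd.DataFrame(rows, columns=["flight_id", "tile_id", "species", "volunteer_id", "count"])


def test_aggregate_all_cardinality_and_values():
    matrix = _matrix({("t1", "seal"): [0, 1, 2, 2, 3], ("t1", "sea_lion"): [0, 0, 0]})
    out = aggregate_all(matrix)
    assert len(out) == 12  # 1 tile x 2 species x 6 algorithms
    m3 = out[(out.species == "seal") & (out.algorithm == "Median[3:Max]")]
    assert m3["value"].item() == 2.0
    assert not m3["fallback_used"].item()
    # a tile counted only as empty is 0 under every algorithm
    empty = out[out.species == "sea_lion"]
    assert (empty["value"] == 0).all()
    assert (empty["n_counters"] == 3).all()


def test_aggregate_all_flags_fallback_and_is_pure():
    matrix = _matrix({("t1", "seal"): [2, 4]})
    first = aggregate_all(matrix)
    again = aggregate_all(matrix)
    pd.testing.assert_frame_equal(first, again)
    trimmed = first[first.algorithm == "Mean[3:Max]"]
    assert trimmed["fallback_used"].item()
    assert trimmed["value"].item() == 3.0


def test_aggregate_all_matches_scalar_path(rng):
    vectors = {
        (f"t{i}", sp): list(rng.integers(0, 30, size=rng.integers(1, 16)))
        for i in range(40)
        for sp in ("seal", "sea_lion")
    }
    out = aggregate_all(_matrix(vectors))
    for row in out.itertuples(index=False):
        assert row.value == oracle(vectors[(row.tile_id, row.species)], row.algorithm)
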