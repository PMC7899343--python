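"""The six trimmed consensus algorithms that collapse repeated counts.

Each subject tile is counted by up to 15 volunteers, giving a vector of
repeated counts per (tile, species). A consensus algorithm collapses that
vector into one number. The six algorithms are the mean and the median, each
applied to the full sorted vector, to the vector with its two smallest
values dropped (``[3:Max]``), and to the vector with its two largest values
dropped (``[1:Max-2]``):

========================  ==========================================
name                      statistic on sorted counts c(1) <= ... <= c(n)
========================  ==========================================
``Mean``                  mean of all n values
``Mean[3:Max]``           mean of c(3)..c(n)    (drop two lowest)
``Mean[1:Max-2]``         mean of c(1)..c(n-2)  (drop two highest)
``Median``                median of all n values
``Median[3:Max]``         median of c(3)..c(n)
``Median[1:Max-2]``       median of c(1)..c(n-2)
========================  ==========================================

Because volunteers systematically undercount, dropping the two lowest
values before taking the median corrects the bias best in practice; the
validation module quantifies this. Trimming is positional on the sorted
vector, so ties need no rule. For n <= 2 a trimmed variant falls back to
its untrimmed statistic and flags the result (``fallback_used``). Medians
of even-length vectors are midpoints — consensus values are deliberately
left fractional, since downstream comparisons use sums and errors, not
discrete counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

ALGORITHMS: tuple[str, ...] = (
    "Mean[3:Max]",
    "Mean",
    "Mean[1:Max-2]",
    "Median[3:Max]",
    "Median",
    "Median[1:Max-2]",
)

_TRIMMED = {"Mean[3:Max]", "Mean[1:Max-2]", "Median[3:Max]", "Median[1:Max-2]"}

__all__ = ["ALGORITHMS", "aggregate", "aggregate_sorted_matrix", "aggregate_all"]


def _check_algorithm(algorithm: str) -> None:
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid names: {', '.join(ALGORITHMS)}"
        )


def aggregate(counts: Sequence[float], algorithm: str) -> float:
    """Collapse one vector of repeated counts into a consensus value.

    Parameters
    ----------
    counts : sequence of numbers
        The repeated volunteer counts for one (tile, species); order is
        irrelevant, the vector is sorted internally. Must be non-empty.
    algorithm : str
        One of :data:`ALGORITHMS`.

    Returns
    -------
    float
        The consensus count. Trimmed variants on vectors of length <= 2
        fall back to the untrimmed statistic (see :func:`uses_fallback`).
    """
    _check_algorithm(algorithm)
    c = np.sort(np.asarray(counts, dtype=float))
    if c.size == 0:
        raise ValueError("cannot aggregate an empty count vector")
    if algorithm in _TRIMMED and c.size > 2:
        c = c[2:] if "[3:Max]" in algorithm else c[:-2]
    if algorithm.startswith("Mean"):
        return float(c.mean())
    return float(np.median(c))


def uses_fallback(n: int, algorithm: str) -> bool:
    """True when a trimmed algorithm cannot trim (n <= 2) and falls back."""
    _check_algorithm(algorithm)
    return algorithm in _TRIMMED and n <= 2


def aggregate_sorted_matrix(sorted_counts: np.ndarray, n: np.ndarray, algorithm: str) -> np.ndarray:
    """Vectorized consensus over many count vectors at once.

    ``sorted_counts`` is a 2-D float array with one row per (tile, species),
    each row sorted ascending with NaN padding on the right; ``n`` gives the
    number of valid entries per row (all >= 1).
    """
    _check_algorithm(algorithm)
    c = np.asarray(sorted_counts, dtype=float)
    n = np.asarray(n, dtype=int)
    if c.ndim != 2 or n.shape != (c.shape[0],) or (n < 1).any():
        raise ValueError("expected a 2-D row-sorted matrix and per-row n >= 1")

    trim = algorithm in _TRIMMED
    can_trim = n > 2
    # start/stop of the slice actually aggregated, per row
    if trim and "[3:Max]" in algorithm:
        start = np.where(can_trim, 2, 0)
        stop = n
    elif trim:
        start = np.zeros_like(n)
        stop = np.where(can_trim, n - 2, n)
    else:
        start = np.zeros_like(n)
        stop = n

    m = stop - start  # effective sample size per row
    if algorithm.startswith("Mean"):
        totals = np.nancumsum(c, axis=1)
        rows = np.arange(c.shape[0])
        hi = totals[rows, stop - 1]
        lo = np.where(start > 0, totals[rows, start - 1], 0.0)
        return (hi - lo) / m
    # median: midpoint of the two central order statistics of the slice
    lo_idx = start + (m - 1) // 2
    hi_idx = start + m // 2
    vals = c[np.arange(c.shape[0]), lo_idx] + c[np.arange(c.shape[0]), hi_idx]
    return vals / 2.0


def aggregate_all(
    count_matrix: pd.DataFrame,
    algorithms: Sequence[str] = ALGORITHMS,
) -> pd.DataFrame:
    """Run every requested algorithm on every (tile, species) count vector.

    Parameters
    ----------
    count_matrix : DataFrame
        Long-format repeated counts with columns ``flight_id, tile_id,
        species, volunteer_id, count``. Species are never pooled: seal and
        sea lion vectors are collapsed independently.
    algorithms : sequence of str
        Algorithm names to run (default: all six).

    Returns
    -------
    DataFrame
        One row per (flight_id, tile_id, species, algorithm) with columns
        ``value``, ``n_counters`` and ``fallback_used``.
    """
    for a in algorithms:
        _check_algorithm(a)
    required = {"flight_id", "tile_id", "species", "volunteer_id", "count"}
    missing = required - set(count_matrix.columns)
    if missing:
        raise ValueError(f"count matrix missing columns: {sorted(missing)}")
    if count_matrix.empty:
        return pd.DataFrame(
            columns=["flight_id", "tile_id", "species", "algorithm", "value",
                     "n_counters", "fallback_used"]
        )
    if (count_matrix["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    keys = ["flight_id", "tile_id", "species"]
    grouped = count_matrix.groupby(keys, sort=True)["count"]
    n = grouped.size().to_numpy()
    group_keys = list(grouped.size().index)
    width = int(n.max())
    mat = np.full((len(n), width), np.nan)
    for i, (_, vals) in enumerate(grouped):
        v = np.sort(vals.to_numpy(dtype=float))
        mat[i, : v.size] = v

    frames = []
    for algorithm in algorithms:
        values = aggregate_sorted_matrix(mat, n, algorithm)
        frames.append(
            pd.DataFrame(
                {
                    "flight_id": [k[0] for k in group_keys],
                    "tile_id": [k[1] for k in group_keys],
                    "species": [k[2] for k in group_keys],
                    "algorithm": algorithm,
                    "value": values,
                    "n_counters": n,
                    "fallback_used": [uses_fallback(int(k), algorithm) for k in n],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
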