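"""Seeded synthetic data: iid null matrices, lead-lag pairs, null tails.

These generators stand in for the kinds of inputs the method targets —
microbial abundance tables, expression profiles, phrase-volume series — with
known structure: either no structure at all (the independence null) or a
single planted lead-lag coupling.  All generators are pure functions of
their spec including the seed; repeat calls agree bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeriesMatrix

__all__ = ["SyntheticSpec", "null_matrix", "lagged_pair", "empirical_null_tail"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the null-matrix generator.

    ``distribution`` is ``uniform01`` (uniform on [0, 1), the null used for
    the large false-positive screens; location/scale are irrelevant after
    standardization) or ``standard_normal``.  ``zero_fraction`` and
    ``missing_fraction`` plant exact zeros and missing flags so the
    preprocessing filters have something to chew on.
    """

    m: int
    n: int
    distribution: str = "uniform01"
    zero_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 2:
            raise ValueError(f"need m >= 1 and n >= 2, got m={self.m}, n={self.n}")
        if self.distribution not in ("uniform01", "standard_normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for name in ("zero_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def null_matrix(spec: SyntheticSpec) -> TimeSeriesMatrix:
    """An m x n matrix of iid draws with no cross-series dependence."""
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "uniform01":
        values = rng.random((spec.m, spec.n))
    else:
        values = rng.standard_normal((spec.m, spec.n))
    if spec.zero_fraction > 0.0:
        values[rng.random(values.shape) < spec.zero_fraction] = 0.0
    mask = np.zeros(values.shape, dtype=bool)
    if spec.missing_fraction > 0.0:
        mask = rng.random(values.shape) < spec.missing_fraction
        # keep every row interpolatable: force >= 2 observed entries
        short = np.flatnonzero((~mask).sum(axis=1) < 2)
        mask[short, :2] = False
        values = values.copy()
        values[mask] = np.nan
    width = len(str(spec.m))
    return TimeSeriesMatrix(
        values=values,
        row_labels=tuple(f"s{i:0{width}d}" for i in range(spec.m)),
        col_labels=tuple(f"t{j}" for j in range(spec.n)),
        missing_mask=mask,
    )


def lagged_pair(
    n: int, lag: int, coupling: float = 1.0, noise_sd: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two raw series where b tracks a at a fixed delay.

    ``a`` is iid standard normal; on the overlap,
    ``b_t = coupling * a_{t-lag} + noise_sd * eps_t``; outside the overlap
    ``b`` is iid noise.  Returns raw (unstandardized) vectors, since the
    pipeline owns standardization.
    """
    if abs(lag) > n - 2:
        raise ValueError(f"need |lag| <= n-2, got lag={lag}, n={n}")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)  # pure-noise baseline, overwritten on overlap
    eps = rng.standard_normal(n)
    t = np.arange(n)
    overlap = (t - lag >= 0) & (t - lag < n)
    b[overlap] = coupling * a[t[overlap] - lag] + noise_sd * eps[overlap]
    return a, b


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    z = values - values.mean(axis=1, keepdims=True)
    z /= z.std(axis=1, keepdims=True)
    return z


def _abs_lsa_batch(x: np.ndarray, y: np.ndarray, D: int) -> np.ndarray:
    """|LSA| for many standardized pairs at once (rows of x against rows of y).

    Runs the reset-at-zero recursion vectorized across pairs, one diagonal
    at a time, tracking the running maxima of the positive and negated
    product sums.
    """
    num, n = x.shape
    best = np.zeros(num)
    for d in range(-D, D + 1):
        if d >= 0:
            z = x[:, d:] * y[:, : n - d]
        else:
            z = x[:, : n + d] * y[:, -d:]
        run_p = np.zeros(num)
        run_n = np.zeros(num)
        for k in range(z.shape[1]):
            zk = z[:, k]
            run_p = np.maximum(0.0, run_p + zk)
            run_n = np.maximum(0.0, run_n - zk)
            np.maximum(best, run_p, out=best)
            np.maximum(best, run_n, out=best)
    return best / n


def empirical_null_tail(
    n: int,
    D: int,
    num_pairs: int,
    grid: np.ndarray,
    seed: int = 0,
    distribution: str = "standard_normal",
) -> np.ndarray:
    """Empirical exceedance of |LSA| over a threshold grid under the null.

    Simulates ``num_pairs`` independent iid pairs, standardizes them, and
    returns ``P(|LSA| > x)`` estimated at each grid value — the Monte-Carlo
    yardstick against which the analytic bound's conservativeness is judged.
    """
    grid = np.asarray(grid, dtype=float)
    if num_pairs < 100:
        raise ValueError(f"num_pairs must be >= 100, got {num_pairs}")
    if grid.ndim != 1 or grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be a non-empty finite 1-D vector")
    rng = np.random.default_rng(seed)
    if distribution == "uniform01":
        x = rng.random((num_pairs, n))
        y = rng.random((num_pairs, n))
    elif distribution == "standard_normal":
        x = rng.standard_normal((num_pairs, n))
        y = rng.standard_normal((num_pairs, n))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    stats = _abs_lsa_batch(_standardize_rows(x), _standardize_rows(y), D)
    return (stats[None, :] > grid[:, None]).mean(axis=1)
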