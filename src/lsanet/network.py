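"""All-pairs LSA over a standardized matrix, significance gating, export.

For m series this evaluates the pairwise statistic for all C(m, 2) unordered
pairs in O(m^2 (2D+1) n) time — no permutations — attaches the analytic
p-value bound to each edge, applies the family-wise correction, and exports
the resulting association network in Cytoscape-friendly formats.

Pairs are enumerated in a fixed canonical order (series sorted by label,
then index pairs i < j) and chunked; chunk results land in preallocated
slices of the output arrays, so the edge table is identical for any number
of workers.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .core import LagWindow, StandardSeries
from .significance import (
    PermutationSpec,
    bonferroni_alpha,
    check_series_length,
    permutation_pvalue,
    pvalue_bound_grid,
)

__all__ = ["EdgeTable", "all_pairs_lsa", "export_network", "significant_graph"]

EXPORT_FORMATS = ("sif", "edge_attr_tsv", "graphml")


@dataclass(frozen=True)
class EdgeTable:
    """All-pairs LSA results plus the run metadata needed to reproduce them.

    ``edges`` has one row per unordered pair with ``label_a < label_b``
    lexicographically; a row is ``significant`` iff its p-value bound is at
    most the corrected alpha and ``|statistic|`` reaches the magnitude
    threshold.
    """

    edges: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"label_a", "label_b", "statistic", "p_bound", "best_lag", "significant"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")

    @property
    def significant(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


@njit(nogil=True, cache=False)
def _pair_kernel(X, ia, ja, D, stats, lags):  # pragma: no cover - numba
    n = X.shape[1]
    for p in range(ia.size):
        xi = X[ia[p]]
        yj = X[ja[p]]
        best_p = 0.0
        best_n = 0.0
        lag_p = 0
        lag_n = 0
        for d in range(-D, D + 1):
            length = n - d if d >= 0 else n + d
            run_p = 0.0
            run_n = 0.0
            for k in range(length):
                v = xi[k + d] * yj[k] if d >= 0 else xi[k] * yj[k - d]
                run_p += v
                if run_p < 0.0:
                    run_p = 0.0
                elif run_p > best_p:
                    best_p = run_p
                    lag_p = d
                run_n -= v
                if run_n < 0.0:
                    run_n = 0.0
                elif run_n > best_n:
                    best_n = run_n
                    lag_n = d
        if best_p >= best_n:
            stats[p] = best_p / n
            lags[p] = lag_p
        else:
            stats[p] = -best_n / n
            lags[p] = lag_n


def all_pairs_lsa(
    series: list[StandardSeries],
    lag: LagWindow = LagWindow(3),
    alpha: float = 0.001,
    correction: str = "bonferroni",
    lsa_threshold: float = 0.0,
    bound_variant: str = "table",
    workers: int = 1,
    perms: int = 0,
    seed: int = 0,
) -> EdgeTable:
    """Evaluate LSA and its p-value bound for every unordered series pair.

    Parameters
    ----------
    series
        Standardized series of equal length; evaluated as all C(m, 2) pairs.
    lag
        Maximum time shift searched per pair.
    alpha, correction
        Significance level and family-wise correction; ``bonferroni``
        divides alpha by the actual number of tests C(m, 2).
    lsa_threshold
        Additional magnitude gate: edges also need ``|statistic|`` at or
        above this to be significant (0 disables it).
    perms
        If positive, a permutation p-value column is added with this many
        permutations per pair, seeded per pair from ``seed`` so results do
        not depend on evaluation order.  Expensive; meant for small m.
    workers
        Thread count for the chunked kernel; output is identical for any
        value.
    """
    m = len(series)
    if m < 2:
        raise ValueError(f"need at least 2 series, got {m}")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise ValueError("all series must have equal length")
    if lag.D > n - 2:
        raise ValueError(f"lag bound D={lag.D} exceeds n-2={n - 2}")
    check_series_length(n)

    order = sorted(range(m), key=lambda i: series[i].label)
    ordered = [series[i] for i in order]
    X = np.ascontiguousarray(np.stack([s.values for s in ordered]))
    ia, ja = np.triu_indices(m, k=1)
    ia = ia.astype(np.int64)
    ja = ja.astype(np.int64)
    num_pairs = ia.size
    stats = np.empty(num_pairs)
    lags = np.empty(num_pairs, dtype=np.int64)

    if workers == 1 or num_pairs < 1024:
        _pair_kernel(X, ia, ja, lag.D, stats, lags)
    else:
        bounds = np.linspace(0, num_pairs, workers * 4 + 1).astype(np.int64)
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = [
                pool.submit(
                    _pair_kernel, X, ia[lo:hi], ja[lo:hi], lag.D, stats[lo:hi], lags[lo:hi]
                )
                for lo, hi in zip(bounds[:-1], bounds[1:])
                if hi > lo
            ]
            for fut in futures:
                fut.result()

    p_bound = pvalue_bound_grid(np.abs(stats), n=n, D=lag.D, variant=bound_variant)
    corrected = (
        bonferroni_alpha(alpha, num_pairs) if correction == "bonferroni" else alpha
    )
    significant = (p_bound <= corrected) & (np.abs(stats) >= lsa_threshold)

    labels = [s.label for s in ordered]
    edges = pd.DataFrame(
        {
            "label_a": [labels[i] for i in ia],
            "label_b": [labels[j] for j in ja],
            "statistic": stats,
            "p_bound": p_bound,
            "best_lag": lags,
            "significant": significant,
        }
    )
    if perms > 0:
        edges["p_perm"] = [
            permutation_pvalue(
                ordered[i], ordered[j], lag, PermutationSpec(perms, seed=seed + k)
            )
            for k, (i, j) in enumerate(zip(ia, ja))
        ]
    meta = {
        "m": m,
        "n": n,
        "D": lag.D,
        "alpha": alpha,
        "correction": correction,
        "corrected_alpha": corrected,
        "lsa_threshold": lsa_threshold,
        "bound_variant": bound_variant,
        "num_pairs": int(num_pairs),
        "num_significant": int(significant.sum()),
        "labels": labels,
    }
    return EdgeTable(edges=edges, meta=meta)


def significant_graph(table: EdgeTable, include_all_nodes: bool = False) -> nx.Graph:
    """Undirected graph of significant edges, with statistic attributes."""
    g = nx.Graph()
    if include_all_nodes:
        g.add_nodes_from(table.meta.get("labels", []))
    for row in table.significant.itertuples(index=False):
        g.add_edge(
            row.label_a,
            row.label_b,
            statistic=float(row.statistic),
            p_bound=float(row.p_bound),
            best_lag=int(row.best_lag),
        )
    return g


def export_network(
    table: EdgeTable, fmt: str, path: str | Path, all_edges: bool = False
) -> Path:
    """Write the edge table as SIF, a TSV attribute table, or GraphML.

    SIF codes the association sign in the interaction type (``+ls`` /
    ``-ls``).  Only significant edges are exported unless ``all_edges``.
    """
    path = Path(path)
    rows = table.edges if all_edges else table.significant
    if fmt == "sif":
        with open(path, "w") as fh:
            for row in rows.itertuples(index=False):
                kind = "+ls" if row.statistic >= 0 else "-ls"
                fh.write(f"{row.label_a}\t{kind}\t{row.label_b}\n")
    elif fmt == "edge_attr_tsv":
        rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(table.meta.get("labels", []))
        for row in rows.itertuples(index=False):
            g.add_edge(
                row.label_a,
                row.label_b,
                statistic=float(row.statistic),
                p_bound=float(row.p_bound),
                best_lag=int(row.best_lag),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    return path
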