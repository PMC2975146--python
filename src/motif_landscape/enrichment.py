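"""Functional-category enrichment of gene subsets.

Each subcluster is tested for over-represented annotation categories
against a universe (by default the starting co-expressed gene set, not the
genome: the question is whether a *subset* is more coherent than the set it
came from).  The test is the hypergeometric upper tail, computed in
log-space; multiple categories are corrected by Benjamini–Hochberg.

Subset results are then compared with the parent set's: a category can be
*new* (significant only in the subset), *improved* (significant in both,
with the subset p smaller by at least a configurable fold — default 100×,
matching the order-of-magnitude gains that motivate subclustering),
*unchanged*, or *absent*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_subset",
    "compare_to_parent",
    "write_enrichment",
]


@dataclass
class EnrichmentRow:
    """One category tested in one subset vs. the universe."""

    category: str
    n_universe: int  # N
    n_category: int  # K: universe genes carrying the category
    n_subset: int  # n: subset size
    n_overlap: int  # x: subset genes carrying the category
    p: float
    q: float = float("nan")
    flagged_single: bool = False  # overlap of 1: reported but flagged


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    lg = math.lgamma

    def lchoose(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        out = np.full(np.broadcast(a, b).shape, -np.inf)
        ok = (b >= 0) & (b <= a)
        av, bv = np.broadcast_to(a, out.shape)[ok], np.broadcast_to(b, out.shape)[ok]
        out[ok] = [
            lg(x + 1) - lg(y + 1) - lg(x - y + 1) for x, y in zip(av, bv)
        ]
        return out

    return lchoose(K, i) + lchoose(N - K, n - i) - lchoose(N, n)


def hypergeom_upper_tail(x: int, K: int, n: int, N: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n), in log-space.

    ``N`` universe genes of which ``K`` carry the category; ``n`` drawn
    (the subset); probability of seeing ``x`` or more carriers.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"bounds violated: K={K}, n={n}, N={N}")
    if not 0 <= x <= min(K, n):
        raise ValueError(f"x={x} outside [0, min(K={K}, n={n})]")
    if x == 0:
        return 1.0
    i = np.arange(x, min(K, n) + 1)
    log_p = float(logsumexp(_log_hypergeom_pmf(i, N, K, n)))
    return min(1.0, math.exp(log_p))


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def enrich_subset(
    subset: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, set[str]],
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of every category present in the subset.

    One row per category with at least one subset member, sorted by p
    ascending then category id; q-values are BH-adjusted across the rows.
    Categories whose subset overlap is exactly 1 are flagged (not dropped).
    """
    subset_set = set(subset)
    universe_set = set(universe)
    if not subset_set <= universe_set:
        extra = sorted(subset_set - universe_set)[:5]
        raise ValueError(f"subset not contained in universe (e.g. {extra})")
    N = len(universe_set)
    n = len(subset_set)
    categories: set[str] = set()
    for g in subset_set:
        categories |= annotation.get(g, set())
    rows: list[EnrichmentRow] = []
    for cat in sorted(categories):
        carriers = {g for g in universe_set if cat in annotation.get(g, set())}
        K = len(carriers)
        x = len(carriers & subset_set)
        rows.append(
            EnrichmentRow(
                category=cat,
                n_universe=N,
                n_category=K,
                n_subset=n,
                n_overlap=x,
                p=hypergeom_upper_tail(x, K, n, N),
                flagged_single=(x == 1),
            )
        )
    rows.sort(key=lambda r: (r.p, r.category))
    for row, q in zip(rows, bh_adjust([r.p for r in rows])):
        row.q = q
    return rows


def compare_to_parent(
    subset_rows: list[EnrichmentRow],
    parent_rows: list[EnrichmentRow],
    fold: float = 100.0,
    fdr: float = 0.05,
) -> dict[str, str]:
    """Classify each subset category against the parent set's enrichment.

    * ``new``: significant in the subset (q < fdr) but not in the parent;
    * ``improved``: significant in both with subset p at least ``fold``
      times smaller;
    * ``unchanged``: significant in both without that gain;
    * ``absent``: not significant in the subset.
    """
    parent = {r.category: r for r in parent_rows}
    status: dict[str, str] = {}
    for row in subset_rows:
        if not row.q < fdr:
            status[row.category] = "absent"
            continue
        prow = parent.get(row.category)
        if prow is None or not prow.q < fdr:
            status[row.category] = "new"
        elif row.p * fold <= prow.p:
            status[row.category] = "improved"
        else:
            status[row.category] = "unchanged"
    return status


def write_enrichment(
    rows_by_subset: Mapping[str, list[EnrichmentRow]],
    status_by_subset: Mapping[str, Mapping[str, str]],
    path: str | Path,
) -> None:
    """Tab-delimited enrichment table across subsets."""
    with open(path, "w", newline="\n") as fh:
        fh.write("subset\tcategory\tN\tK\tn\tx\tp\tq\tstatus\tflag\n")
        for subset in sorted(rows_by_subset):
            for r in rows_by_subset[subset]:
                status = status_by_subset.get(subset, {}).get(r.category, "")
                flag = "single_gene" if r.flagged_single else ""
                fh.write(
                    f"{subset}\t{r.category}\t{r.n_universe}\t{r.n_category}\t"
                    f"{r.n_subset}\t{r.n_overlap}\t{r.p:.6g}\t{r.q:.6g}\t{status}\t{flag}\n"
                )
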