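"""Shared fixtures and independent oracles.

The oracle functions here deliberately re-derive quantities from first
principles (naive scanning, exact combinatorics via Fractions, exhaustive
enumeration) without touching the package's implementation paths, so tests
can compare the two routes.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from motif_landscape.io_formats import GeneSet

# Independent IUPAC table (kept separate from the package's on purpose).
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_ORACLE_COMP[c] for c in reversed(s))


def oracle_window_matches(seq: str, consensus: str) -> list[int]:
    """Naive position-by-position scan; sequence N matches nothing."""
    hits = []
    w = len(consensus)
    for i in range(len(seq) - w + 1):
        ok = True
        for j, sym in enumerate(consensus):
            if seq[i + j] not in ORACLE_IUPAC[sym]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


def oracle_scan(consensus: str, genes: GeneSet, both_strands: bool = True):
    """Brute-force re-derivation of all occurrences with the package's
    distance/strand conventions (dedup of double-orientation windows)."""
    out = []
    rc = oracle_revcomp(consensus)
    for g in genes.genes:
        seq = genes.upstream[g]
        M = len(seq)
        w = len(consensus)
        fwd = oracle_window_matches(seq, consensus)
        hits = [(i, "+") for i in fwd]
        if both_strands and rc != consensus:
            hits += [(i, "-") for i in oracle_window_matches(seq, rc) if i not in set(fwd)]
        out.extend((g, M - (i + w - 1), s) for i, s in hits)
    return out


def oracle_log10_binom_tail(k: int, n: int, p: float) -> float:
    """log10 P[X >= k], X ~ Binomial(n, p): full log-space term summation
    with a manual max-subtraction (no scipy)."""
    if k <= 0:
        return 0.0
    lp, lq = math.log(p), math.log1p(-p)
    logs = [
        math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
        + x * lp + (n - x) * lq
        for x in range(k, n + 1)
    ]
    mx = max(logs)
    return (mx + math.log(math.fsum(math.exp(v - mx) for v in logs))) / math.log(10.0)


def oracle_hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """Exact P[X >= x] via Fraction arithmetic on binomial coefficients."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(x, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def oracle_align(query: np.ndarray, target: np.ndarray, min_overlap: int = 4):
    """Exhaustive (score, offset, orientation) enumeration, written plainly."""
    def rc(p):
        return np.array([[row[3], row[2], row[1], row[0]] for row in p[::-1]])

    wq, wt = len(query), len(target)
    need = min(min_overlap, wq, wt)
    results = []
    for orient, tgt in (("+", target), ("-", rc(target))):
        for offset in range(-(wq - 1), wt):
            cols = []
            for qi in range(wq):
                ti = qi + offset
                if 0 <= ti < wt:
                    cols.append(
                        math.sqrt(sum((query[qi][b] - tgt[ti][b]) ** 2 for b in range(4)))
                    )
            if len(cols) >= need:
                results.append(
                    (sum(cols) / len(cols), -len(cols), abs(offset),
                     0 if orient == "+" else 1, offset, orient)
                )
    best = min(results)
    return best[0], best[4], best[5]


def oracle_grid_ascent(values: np.ndarray, iy: int, ix: int) -> tuple[int, int]:
    """Exhaustive steepest ascent to a local maximum on the 8-neighbour grid."""
    ny, nx = values.shape
    while True:
        best, best_v = (iy, ix), values[iy, ix]
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < ny and 0 <= jx < nx and values[jy, jx] > best_v:
                    best, best_v = (jy, jx), values[jy, jx]
        if best == (iy, ix):
            return best
        iy, ix = best


@pytest.fixture
def tiny_gene_set() -> GeneSet:
    return GeneSet(
        genes=["g1", "g2"],
        upstream={
            "g1": "ACGTACGTACGTACGTACGT",
            "g2": "TTTTACGCGTTTTTTTTTTT",
        },
        region_length=20,
    )
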