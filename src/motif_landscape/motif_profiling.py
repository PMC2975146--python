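"""Quartile analysis: motif reports → positional gene-motif vectors.

The upstream window (default 800 bp) is divided into equal bins (default 4
bins of 200 bp — the quartiles).  Each gene becomes a vector of per-(motif,
bin) occurrence counts; genes with similar motif content *and* similar
positional distributions then sit close together under the profile metric
and can be clustered.

Bins are half-open on the left — (0,200], (200,400], … — so the 1-based
upstream distance d falls in bin ceil(d / bin_width), with bin 1 closest to
the gene start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import FormatError, GeneSet, MotifReportRow

__all__ = ["ProfileMatrix", "bin_of", "build_profile_matrix", "profile_distance"]


def bin_of(distance: int, bin_width: int, n_bins: int) -> int:
    """Bin index (1-based) of an upstream distance; bin 1 is nearest the start."""
    if bin_width < 1 or n_bins < 1:
        raise ValueError("bin_width and n_bins must be >= 1")
    if not 1 <= distance <= bin_width * n_bins:
        raise ValueError(
            f"distance {distance} outside [1, {bin_width * n_bins}]"
        )
    return math.ceil(distance / bin_width)


@dataclass
class ProfileMatrix:
    """Genes × (motif, bin) occurrence-count matrix.

    ``counts`` has one row per gene and ``len(motifs) * n_bins`` columns in
    motif-major order (all bins of motif 1, then motif 2, ...); bins ascend
    from the gene start.  Column labels read ``consensus@bin<i>``.
    """

    genes: list[str]
    motifs: list[str]
    n_bins: int
    bin_width: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        expected = (len(self.genes), len(self.motifs) * self.n_bins)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def column_labels(self) -> list[str]:
        return [
            f"{m}@bin{b}" for m in self.motifs for b in range(1, self.n_bins + 1)
        ]

    def row(self, gene: str) -> np.ndarray:
        return self.counts[self.genes.index(gene)]

    def zero_genes(self) -> list[str]:
        """Genes with no occurrence of any motif (all-zero rows)."""
        mask = self.counts.sum(axis=1) == 0
        return [g for g, z in zip(self.genes, mask) if z]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.column_labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        with open(path, "w", newline="\n") as fh:
            fh.write(f"# bin_width={self.bin_width}\n")
            df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        bin_width = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# bin_width="):
                bin_width = int(first.strip().split("=", 1)[1])
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        motifs: list[str] = []
        bins: list[int] = []
        for col in df.columns:
            m, _, b = col.rpartition("@bin")
            if not m or not b.isdigit():
                raise FormatError(f"{path}: bad profile column {col!r}")
            if m not in motifs:
                motifs.append(m)
            bins.append(int(b))
        n_bins = max(bins) if bins else 4
        expected = [f"{m}@bin{b}" for m in motifs for b in range(1, n_bins + 1)]
        if list(df.columns) != expected:
            raise FormatError(f"{path}: profile columns out of canonical order")
        return cls(
            genes=[str(g) for g in df.index],
            motifs=motifs,
            n_bins=n_bins,
            bin_width=bin_width,
            counts=df.to_numpy(),
        )


def build_profile_matrix(
    report: list[MotifReportRow], genes: GeneSet, n_bins: int = 4
) -> ProfileMatrix:
    """Bin every report occurrence into the gene × (motif, bin) count table.

    The region length must divide evenly into ``n_bins``; genes without any
    occurrence keep an all-zero row (they are later labelled "unclustered"
    rather than dropped, so coverage accounting stays honest).
    """
    if genes.region_length % n_bins != 0:
        raise ValueError(
            f"region_length {genes.region_length} not divisible by n_bins {n_bins}"
        )
    bin_width = genes.region_length // n_bins
    motifs = [row.consensus for row in report]
    if len(set(motifs)) != len(motifs):
        raise ValueError("duplicate consensus in report")
    gene_index = {g: i for i, g in enumerate(genes.genes)}
    counts = np.zeros((len(genes.genes), len(motifs) * n_bins), dtype=int)
    for mi, row in enumerate(report):
        for gene, dist, _strand in row.occurrences:
            if gene not in gene_index:
                raise ValueError(
                    f"occurrence gene {gene!r} (motif {row.consensus}) not in gene set"
                )
            b = bin_of(dist, bin_width, n_bins)
            counts[gene_index[gene], mi * n_bins + (b - 1)] += 1
    return ProfileMatrix(
        genes=list(genes.genes),
        motifs=motifs,
        n_bins=n_bins,
        bin_width=bin_width,
        counts=counts,
    )


def profile_distance(u: np.ndarray, v: np.ndarray, metric: str = "cosine") -> float:
    """Distance between two gene-motif vectors.

    Cosine distance is 1 − cos(u, v), with distance(0-vector, anything) = 1
    by convention; euclidean is the standard norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            return 1.0
        return float(1.0 - np.dot(u, v) / (nu * nv))
    raise ValueError(f"unknown metric {metric!r}")
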