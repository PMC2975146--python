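"""Self-contained synthetic fixtures emulating the pipeline's inputs.

The generator produces upstream regions from a low-order Markov background,
plants motif instances into designated gene subsets with controlled
per-quartile positional distributions (the situation where subsets share a
sequence core but differ in where it sits relative to the gene start), and
fabricates the two side tables real analyses pull from external resources:
a gene→category annotation with subset-enriched categories, and a motif
database that contains the planted motifs under known regulator-style
names.  Every output is a deterministic function of (scenario, seed) and
the manifest records enough to regenerate it bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    BASES,
    IUPAC,
    GeneSet,
    revcomp,
    validate_consensus,
    write_annotation,
    write_gene_set,
    write_motif_db,
)
from .motif_discovery import Background
from .motif_matching import consensus_to_pwm

__all__ = [
    "PlantSpec",
    "FixtureBundle",
    "sample_background",
    "plant_motifs",
    "make_annotation",
    "make_fixture",
    "SCENARIOS",
]


@dataclass
class PlantSpec:
    """How one subset's motif is planted.

    ``occurrences_per_gene``: an int plants exactly that many instances per
    gene; a float is a Poisson rate.  ``quartile_weights`` give the
    probability of each upstream bin (bin 1 nearest the gene start); every
    instance is placed entirely inside its sampled bin.
    """

    subset_id: str
    n_genes: int
    consensus: str
    occurrences_per_gene: int | float = 2
    quartile_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    strand_prob_plus: float = 0.5

    def __post_init__(self) -> None:
        validate_consensus(self.consensus)
        w = np.asarray(self.quartile_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("quartile_weights must be non-negative and sum to 1")
        if not 0.0 <= self.strand_prob_plus <= 1.0:
            raise ValueError("strand_prob_plus must be in [0, 1]")


def sample_background(
    n_genes: int, L: int, bg: Background | None = None, seed: int = 0,
    prefix: str = "g",
) -> GeneSet:
    """i.i.d. (order-0) or Markov (order-1) background upstream sequences."""
    if n_genes < 0 or L < 1:
        raise ValueError("need n_genes >= 0 and L >= 1")
    if bg is None:
        bg = Background()
    rng = np.random.default_rng([seed, 101])
    genes = [f"{prefix}{i + 1:03d}" for i in range(n_genes)]
    upstream: dict[str, str] = {}
    base_arr = np.array(list(BASES))
    for g in genes:
        if bg.order == 0:
            codes = rng.choice(4, size=L, p=bg.base_freqs)
        else:
            codes = np.empty(L, dtype=int)
            codes[0] = rng.choice(4, p=bg.base_freqs)
            for i in range(1, L):
                codes[i] = rng.choice(4, p=bg.transitions[codes[i - 1]])
        upstream[g] = "".join(base_arr[codes])
    return GeneSet(genes, upstream, region_length=L)


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC[c])) for c in consensus)


def plant_motifs(
    genes: GeneSet,
    specs: list[PlantSpec],
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[GeneSet, dict[str, str]]:
    """Overwrite background with motif instances; return (genes, truth labels).

    Subsets take genes in order and must partition the gene set exactly.
    Instances never overlap within a gene (positions are rejection-sampled);
    placement keeps the region length fixed because instances overwrite
    rather than insert.
    """
    if sum(s.n_genes for s in specs) != len(genes):
        raise ValueError("plant specs must partition the gene set")
    rng = np.random.default_rng([seed, 202])
    L = genes.region_length
    upstream = dict(genes.upstream)
    truth: dict[str, str] = {}
    cursor = 0
    for spec in specs:
        w = len(spec.consensus)
        n_bins = len(spec.quartile_weights)
        if L % n_bins != 0:
            raise ValueError("region length not divisible by bin count")
        width = L // n_bins
        if w > width:
            raise ValueError(f"consensus {spec.consensus} does not fit in one bin")
        members = genes.genes[cursor : cursor + spec.n_genes]
        cursor += spec.n_genes
        for g in members:
            truth[g] = spec.subset_id
            if isinstance(spec.occurrences_per_gene, int):
                n_occ = spec.occurrences_per_gene
            else:
                n_occ = int(rng.poisson(spec.occurrences_per_gene))
            seq = list(upstream[g])
            M = len(seq)
            occupied: list[tuple[int, int]] = []
            for _ in range(n_occ):
                placed = False
                for _retry in range(max_retries):
                    b = int(rng.choice(n_bins, p=spec.quartile_weights)) + 1
                    # distance d of the base nearest the start; instance spans
                    # distances d..d+w-1, kept inside bin b
                    d = int(rng.integers((b - 1) * width + 1, b * width - w + 2))
                    start = M - d - w + 1  # sequence index of the window
                    if any(start <= e and s <= start + w - 1 for s, e in occupied):
                        continue
                    inst = _instantiate(spec.consensus, rng)
                    if rng.random() >= spec.strand_prob_plus:
                        inst = revcomp(inst)
                    seq[start : start + w] = inst
                    occupied.append((start, start + w - 1))
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place {spec.consensus} in {g} without overlap"
                    )
            upstream[g] = "".join(seq)
    return GeneSet(list(genes.genes), upstream, L), truth


def make_annotation(
    truth: dict[str, str],
    n_categories_per_subset: int = 1,
    background_categories: int = 2,
    noise_rate: float = 0.0,
    category_coverage: float = 1.0,
    background_rate: float = 0.3,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Annotation table with subset-private and background categories.

    Each subset gets private categories covering ``category_coverage`` of
    its genes; ``noise_rate`` adds each private category to outside genes at
    that rate; background categories hit every gene at ``background_rate``.
    """
    for rate in (noise_rate, category_coverage, background_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng([seed, 303])
    genes = sorted(truth)
    subsets = sorted(set(truth.values()))
    annotation: dict[str, set[str]] = {g: set() for g in genes}
    for subset in subsets:
        for j in range(n_categories_per_subset):
            cat = f"{subset}_cat{j + 1}"
            for g in genes:
                if truth[g] == subset:
                    if rng.random() < category_coverage:
                        annotation[g].add(cat)
                elif rng.random() < noise_rate:
                    annotation[g].add(cat)
    for j in range(background_categories):
        cat = f"bg_cat{j + 1}"
        for g in genes:
            if rng.random() < background_rate:
                annotation[g].add(cat)
    return {g: cats for g, cats in annotation.items() if cats}


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus ground truth and manifest."""

    genes: GeneSet
    truth: dict[str, str]
    annotation: dict[str, set[str]]
    motif_db: list[tuple[str, np.ndarray]]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "upstream.fasta",
            "truth": out / "truth.tsv",
            "annotation": out / "annotation.tsv",
            "motif_db": out / "motifs.meme",
            "manifest": out / "manifest.json",
        }
        write_gene_set(self.genes, paths["fasta"])
        with open(paths["truth"], "w", newline="\n") as fh:
            fh.write("gene\tsubset\n")
            for g in self.genes.genes:
                fh.write(f"{g}\t{self.truth[g]}\n")
        write_annotation(self.annotation, paths["annotation"])
        write_motif_db(self.motif_db, paths["motif_db"])
        with open(paths["manifest"], "w", newline="\n") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


# Scenario presets.  Motif consensi share the CGCG core across subsets; what
# separates subsets is *where* the core sits (which quartile), mirroring
# co-expressed yeast gene sets whose subclusters carry the same core at
# different upstream distances.  Two instances per gene keep a subset motif
# clearly above the background expectation of the full gene set.
SCENARIOS: dict[str, dict] = {
    "paper_like_g1s": {
        "n_per_subset": 15,
        "L": 800,
        "plants": [
            ("A", "TTACGCGA", (0.0, 0.0, 0.5, 0.5), "SBF-like"),
            ("B", "ATCGCGAA", (0.0, 1.0, 0.0, 0.0), "MCB-like"),
            ("C", "AACGCGTT", (1.0, 0.0, 0.0, 0.0), "MBF-like"),
        ],
        "occurrences_per_gene": 2,
    },
    "two_subsets_shared_core": {
        "n_per_subset": 15,
        "L": 800,
        "plants": [
            ("A", "ATCGCGAA", (0.0, 1.0, 0.0, 0.0), "MBF-like"),
            ("B", "TTACGCGA", (1.0, 0.0, 0.0, 0.0), "SBF-like"),
        ],
        "occurrences_per_gene": 2,
    },
    "null": {
        "n_per_subset": 20,
        "L": 800,
        "plants": [],
        "occurrences_per_gene": 0,
    },
}


def make_fixture(scenario: str, seed: int = 0) -> FixtureBundle:
    """Generate one of the preset scenarios, bit-identically per (name, seed)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; know {sorted(SCENARIOS)}")
    preset = SCENARIOS[scenario]
    plants = preset["plants"]
    n_subsets = max(1, len(plants))
    n_genes = preset["n_per_subset"] * n_subsets
    genes = sample_background(n_genes, preset["L"], seed=seed)
    specs = [
        PlantSpec(
            subset_id=sid,
            n_genes=preset["n_per_subset"],
            consensus=consensus,
            occurrences_per_gene=preset["occurrences_per_gene"],
            quartile_weights=weights,
        )
        for sid, consensus, weights, _name in plants
    ]
    if specs:
        genes, truth = plant_motifs(genes, specs, seed=seed)
    else:
        truth = {g: "S1" for g in genes.genes}
    annotation = make_annotation(
        truth,
        n_categories_per_subset=1,
        background_categories=2,
        noise_rate=0.05,
        category_coverage=0.9,
        seed=seed,
    )
    if plants:
        motif_db = [(name, consensus_to_pwm(c)) for _sid, c, _w, name in plants]
    else:
        # a null run still needs a database to match against
        motif_db = [
            ("MBF-like", consensus_to_pwm("ACGCGT")),
            ("SBF-like", consensus_to_pwm("CRCGAAA")),
        ]
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "L": preset["L"],
        "n_genes": n_genes,
        "plants": [
            {
                "subset": sid,
                "consensus": c,
                "quartile_weights": list(w),
                "db_name": name,
                "occurrences_per_gene": preset["occurrences_per_gene"],
            }
            for sid, c, w, name in plants
        ],
        "annotation": {
            "n_categories_per_subset": 1,
            "background_categories": 2,
            "noise_rate": 0.05,
            "category_coverage": 0.9,
            "background_rate": 0.3,
        },
    }
    return FixtureBundle(genes, truth, annotation, motif_db, manifest)
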