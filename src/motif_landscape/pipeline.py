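"""End-to-end orchestration: discover → profile → cluster → per-subset
re-discovery, enrichment and database matching.

Every stage writes its standard file format into the run directory, so each
stage can also be re-run standalone on the orchestrator's own outputs; the
run summary (JSON) records the stage outputs, per-subset highlights and a
hash of the configuration.  Given a fixed seed the whole run is
deterministic and contains no timestamps, so re-running a config
byte-reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import landscape_clustering as lc
from . import motif_matching as mm
from .io_formats import (
    GeneSet,
    read_annotation,
    read_gene_set,
    read_motif_db,
    write_motif_report,
)
from .motif_discovery import Background, CandidateSpec, discover_motifs, estimate_background
from .motif_profiling import build_profile_matrix
from .synthetic_data import make_fixture

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "load_config"]

log = logging.getLogger("motif_landscape")


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data})


@dataclass
class DiscoveryConfig:
    k_min: int = 5
    k_max: int = 8
    max_degenerate_positions: int = 3
    gap_min: int = 4
    gap_max: int = 10
    top_m: int = 25
    min_sig: float = 2.0
    bg_order: int = 0
    both_strands: bool = True


@dataclass
class ProfileConfig:
    n_bins: int = 4


@dataclass
class ClusterConfig:
    k_neighbors: int = 10
    min_prominence: float = 0.1
    bandwidth: float | None = None
    grid_size: int = 96
    metric: str = "cosine"


@dataclass
class EnrichmentConfig:
    fold: float = 100.0
    fdr: float = 0.05


@dataclass
class MatchConfig:
    n_shuffles: int = 500
    threshold_evalue: float | None = None
    pseudo: float = 0.01


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-serializable; unknown keys rejected).

    Inputs are either real files (``fasta`` + optional ``annotation`` /
    ``motif_db`` / ``universe``) or a synthetic ``scenario`` generated into
    the run directory.  ``universe``, when given, is a gene-id list file
    used as the enrichment universe; otherwise the starting gene set is the
    universe and parent-set enrichment is degenerate (every subset category
    is "new" rather than "improved").
    """

    out_dir: str = "run"
    fasta: str | None = None
    scenario: str | None = None
    annotation: str | None = None
    motif_db: str | None = None
    universe: str | None = None
    region_length: int = 800
    seed: int = 0
    min_subset_size: int = 5
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    match: MatchConfig = field(default_factory=MatchConfig)

    def __post_init__(self) -> None:
        if self.fasta is None and self.scenario is None:
            raise ValueError("config needs either 'fasta' or 'scenario'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are: excluded so the
        # same analysis in two directories hashes (and byte-compares) equal
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key, sub in (
        ("discovery", DiscoveryConfig),
        ("profile", ProfileConfig),
        ("cluster", ClusterConfig),
        ("enrichment", EnrichmentConfig),
        ("match", MatchConfig),
    ):
        if key in data and isinstance(data[key], dict):
            data[key] = _from_dict(sub, data[key])
    return _from_dict(RunConfig, data)


@dataclass
class RunSummary:
    """Machine-readable run record; see ``to_json`` for the on-disk shape."""

    config_hash: str
    paths: dict[str, str]
    n_genes: int
    n_motifs: int
    n_candidates_scored: int
    subsets: list[dict]
    labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "paths": self.paths,
            "n_genes": self.n_genes,
            "n_motifs": self.n_motifs,
            "n_candidates_scored": self.n_candidates_scored,
            "n_subsets": len(self.subsets),
            "subsets": self.subsets,
            "labels": dict(sorted(self.labels.items())),
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


class _Stage:
    """Context manager logging a stage name and wall time to stderr."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            return False
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


def _candidate_spec(cfg: DiscoveryConfig) -> CandidateSpec:
    return CandidateSpec(
        k_min=cfg.k_min,
        k_max=cfg.k_max,
        max_degenerate_positions=cfg.max_degenerate_positions,
        gap_min=cfg.gap_min,
        gap_max=cfg.gap_max,
        both_strands=cfg.both_strands,
    )


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full flow and return the summary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    with _Stage("inputs"):
        annotation: dict[str, set[str]] = {}
        motif_db: list = []
        if config.scenario is not None:
            bundle = make_fixture(config.scenario, seed=config.seed)
            fixture_paths = bundle.write(out / "fixture")
            paths.update({f"fixture_{k}": str(v) for k, v in fixture_paths.items()})
            genes = bundle.genes
            annotation = bundle.annotation
            motif_db = bundle.motif_db
        else:
            genes = read_gene_set(config.fasta, config.region_length)
            if config.annotation:
                annotation = read_annotation(config.annotation)
            if config.motif_db:
                motif_db = read_motif_db(config.motif_db)
        if config.universe:
            with open(config.universe) as fh:
                universe = {line.strip() for line in fh if line.strip()}
            if not set(genes.genes) <= universe:
                raise ValueError("universe file does not contain the gene set")
        else:
            universe = set(genes.genes)

    # ---- discovery on the full set ---------------------------------------
    with _Stage("discover"):
        spec = _candidate_spec(config.discovery)
        bg = estimate_background(genes, order=config.discovery.bg_order)
        report = discover_motifs(
            genes, spec, bg, top_m=config.discovery.top_m,
            min_sig=config.discovery.min_sig,
        )
        paths["report"] = str(out / "report.tsv")
        write_motif_report(
            report, paths["report"],
            region_length=genes.region_length,
            n_candidates_scored=spec.max_candidates_scored,
        )
        log.info("discovered %d motifs (C=%s)", len(report), spec.max_candidates_scored)

    # ---- profiles and clustering -----------------------------------------
    labels: dict[str, str] = {g: lc.UNCLUSTERED for g in genes.genes}
    result = None
    profiles = build_profile_matrix(report, genes, n_bins=config.profile.n_bins)
    paths["profiles"] = str(out / "profiles.tsv")
    profiles.to_tsv(paths["profiles"])
    if report and profiles.counts.sum() > 0:
        with _Stage("cluster"):
            params = lc.LayoutParams(
                k_neighbors=config.cluster.k_neighbors, seed=config.seed
            )
            result = lc.cluster_genes(
                profiles,
                params,
                bandwidth=config.cluster.bandwidth,
                min_prominence=config.cluster.min_prominence,
                metric=config.cluster.metric,
                grid_size=config.cluster.grid_size,
            )
            labels = result.labels
            paths["landscape"] = str(out / "landscape.json")
            paths["labels"] = str(out / "labels.tsv")
            result.to_json(paths["landscape"])
            result.write_labels(paths["labels"])
            log.info("landscape: %d peaks", result.n_clusters())
    else:
        log.info("no significant motifs; all genes left unclustered")

    # ---- parent enrichment ------------------------------------------------
    parent_rows = (
        enr.enrich_subset(set(genes.genes), universe, annotation) if annotation else []
    )

    # ---- per-subset analysis ----------------------------------------------
    subset_summaries: list[dict] = []
    rows_by_subset: dict[str, list] = {}
    status_by_subset: dict[str, dict[str, str]] = {}
    peak_ids = sorted({p for p in labels.values() if p != lc.UNCLUSTERED})
    for peak_id in peak_ids:
        members = sorted(g for g, p in labels.items() if p == peak_id)
        entry: dict[str, Any] = {"subset": peak_id, "n_genes": len(members)}
        if len(members) < config.min_subset_size:
            entry["skipped"] = f"fewer than {config.min_subset_size} genes"
            subset_summaries.append(entry)
            continue
        with _Stage(f"subset:{peak_id}"):
            sub_genes = genes.subset(members)
            sub_spec = _candidate_spec(config.discovery)
            sub_bg = estimate_background(sub_genes, order=config.discovery.bg_order)
            sub_report = discover_motifs(
                sub_genes, sub_spec, sub_bg,
                top_m=config.discovery.top_m, min_sig=config.discovery.min_sig,
            )
            sub_dir = out / f"subset_{peak_id}"
            sub_dir.mkdir(exist_ok=True)
            paths[f"subset_{peak_id}_report"] = str(sub_dir / "report.tsv")
            write_motif_report(
                sub_report, paths[f"subset_{peak_id}_report"],
                region_length=genes.region_length,
                n_candidates_scored=sub_spec.max_candidates_scored,
            )
            entry["top_motifs"] = [
                {"consensus": r.consensus, "sig": r.sig, "coverage": r.coverage}
                for r in sub_report[:5]
            ]
            if annotation:
                rows = enr.enrich_subset(set(members), universe, annotation)
                status = enr.compare_to_parent(
                    rows, parent_rows,
                    fold=config.enrichment.fold, fdr=config.enrichment.fdr,
                )
                rows_by_subset[peak_id] = rows
                status_by_subset[peak_id] = status
                entry["enriched_categories"] = [
                    {"category": r.category, "p": r.p, "q": r.q,
                     "status": status[r.category]}
                    for r in rows
                    if r.q < config.enrichment.fdr
                ]
            if motif_db and sub_report:
                matches = mm.match_report(
                    sub_report, motif_db,
                    threshold_evalue=config.match.threshold_evalue,
                    n_shuffles=config.match.n_shuffles,
                    seed=config.seed,
                    pseudo=config.match.pseudo,
                )
                paths[f"subset_{peak_id}_matches"] = str(sub_dir / "matches.tsv")
                mm.write_matches(matches, paths[f"subset_{peak_id}_matches"])
                entry["top_matches"] = [
                    {"motif": m.query, "target": m.target, "evalue": m.evalue,
                     "coverage": m.coverage}
                    for m in matches[:5]
                ]
        subset_summaries.append(entry)

    if rows_by_subset:
        paths["enrichment"] = str(out / "enrichment.tsv")
        enr.write_enrichment(rows_by_subset, status_by_subset, paths["enrichment"])

    for p in paths.values():
        assert Path(p).exists(), f"stage output missing: {p}"
    rel_paths = {k: str(Path(p).relative_to(out)) for k, p in sorted(paths.items())}
    summary = RunSummary(
        config_hash=config.config_hash(),
        paths=rel_paths,
        n_genes=len(genes),
        n_motifs=len(report),
        n_candidates_scored=spec.max_candidates_scored or 0,
        subsets=subset_summaries,
        labels=labels,
    )
    summary.to_json(out / "summary.json")
    return summary
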