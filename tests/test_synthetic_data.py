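"""Fixture generator: backgrounds, planting, annotation, scenarios."""

import numpy as np
import pytest
from conftest import oracle_hypergeom_tail, oracle_scan

from motif_landscape.motif_discovery import scan_consensus
from motif_landscape.synthetic_data import (
    SCENARIOS,
    PlantSpec,
    make_annotation,
    make_fixture,
    plant_motifs,
    sample_background,
)


def test_background_empty_and_deterministic():
    assert len(sample_background(0, 800, seed=1)) == 0
    a = sample_background(3, 200, seed=9)
    b = sample_background(3, 200, seed=9)
    assert a.upstream == b.upstream
    c = sample_background(3, 200, seed=10)
    assert a.upstream != c.upstream


def test_background_base_frequencies_near_uniform():
    genes = sample_background(200, 800, seed=4)
    joined = "".join(genes.upstream.values())
    for base in "ACGT":
        assert joined.count(base) / len(joined) == pytest.approx(0.25, abs=0.02)


def test_planting_respects_quartile_weights():
    genes = sample_background(30, 800, seed=6)
    spec = PlantSpec("A", 30, "ACGCGTAC", occurrences_per_gene=2,
                     quartile_weights=(0.0, 1.0, 0.0, 0.0))
    planted, truth = plant_motifs(genes, [spec], seed=6)
    assert set(truth.values()) == {"A"}
    hits = scan_consensus("ACGCGTAC", planted)
    planted_hits = [d for _, d, _ in hits if 200 < d <= 400]
    # every gene carries both instances inside quartile 2
    assert len(hits) >= 60 and len(planted_hits) >= 60


def test_plus_strand_plant_is_verbatim():
    genes = sample_background(10, 400, seed=2)
    spec = PlantSpec("A", 10, "ACGCGTAC", occurrences_per_gene=1,
                     quartile_weights=(1.0, 0.0), strand_prob_plus=1.0)
    planted, _ = plant_motifs(genes, [spec], seed=2)
    assert all("ACGCGTAC" in s for s in planted.upstream.values())


def test_planted_bin_fractions_concentrate():
    # 500 genes x 2 plants with weights (0.5, 0.5, 0, 0)
    genes = sample_background(500, 800, seed=8)
    spec = PlantSpec("A", 500, "ACGCGTAC", occurrences_per_gene=2,
                     quartile_weights=(0.5, 0.5, 0.0, 0.0))
    planted, _ = plant_motifs(genes, [spec], seed=8)
    dists = [d for _, d, _ in oracle_scan("ACGCGTAC", planted)]
    in_bin1 = sum(1 for d in dists if d <= 200) / len(dists)
    assert in_bin1 == pytest.approx(0.5, abs=0.05)
    # only chance background occurrences (expected ~1%) fall beyond bin 2
    assert sum(1 for d in dists if d > 400) / len(dists) <= 0.03


def test_plant_specs_must_partition():
    genes = sample_background(10, 800, seed=1)
    with pytest.raises(ValueError, match="partition"):
        plant_motifs(genes, [PlantSpec("A", 7, "ACGT")], seed=1)


def test_overcrowded_planting_fails_loudly():
    genes = sample_background(2, 40, seed=1)
    spec = PlantSpec("A", 2, "ACGTACGTAC", occurrences_per_gene=4,
                     quartile_weights=(1.0,))
    with pytest.raises(RuntimeError, match="overlap"):
        plant_motifs(genes, [spec], seed=1)


def test_annotation_exact_membership_at_full_coverage():
    truth = {f"g{i}": ("A" if i < 5 else "B") for i in range(10)}
    ann = make_annotation(truth, n_categories_per_subset=1,
                          background_categories=0, noise_rate=0.0,
                          category_coverage=1.0, seed=3)
    a_members = {g for g, cats in ann.items() if "A_cat1" in cats}
    assert a_members == {g for g, s in truth.items() if s == "A"}


def test_annotation_private_category_is_enrichable():
    truth = {f"g{i:02d}": ("A", "B", "C")[i // 15] for i in range(45)}
    ann = make_annotation(truth, 1, 0, 0.0, 1.0, seed=1)
    # subset of 15, universe 45, category covers exactly the subset
    p = oracle_hypergeom_tail(15, 15, 15, 45)
    assert p < 0.01


def test_annotation_zero_categories_empty():
    truth = {"g1": "A"}
    assert make_annotation(truth, 0, 0, seed=1) == {}


@pytest.mark.parametrize("scenario", sorted(SCENARIOS))
def test_fixture_regeneration_is_bit_identical(tmp_path, scenario):
    d1, d2 = tmp_path / "one", tmp_path / "two"
    make_fixture(scenario, seed=3).write(d1)
    make_fixture(scenario, seed=3).write(d2)
    for p1 in sorted(d1.iterdir()):
        assert p1.read_bytes() == (d2 / p1.name).read_bytes()


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        make_fixture("nope", seed=0)


def test_shared_core_scenario_motifs_share_core():
    b = make_fixture("two_subsets_shared_core", seed=1)
    consensi = [p["consensus"] for p in b.manifest["plants"]]
    assert len(consensi) == 2
    assert all("CGCG" in c for c in consensi)


def test_null_scenario_is_single_subset_background():
    b = make_fixture("null", seed=5)
    assert set(b.truth.values()) == {"S1"}
    assert b.manifest["plants"] == []
    assert len(b.motif_db) >= 1


def test_g1s_scenario_shape():
    b = make_fixture("paper_like_g1s", seed=2)
    assert len(b.genes) == 45
    assert sorted(set(b.truth.values())) == ["A", "B", "C"]
    names = {p["db_name"] for p in b.manifest["plants"]}
    assert names == {"SBF-like", "MCB-like", "MBF-like"}
    # every gene in exactly one subset
    assert set(b.truth) == set(b.genes.genes)
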