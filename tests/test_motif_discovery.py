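"""Motif discovery: scanning, the binomial Sig score, and planted recovery."""

import math

import numpy as np
import pytest
from conftest import (
    ORACLE_IUPAC,
    oracle_log10_binom_tail,
    oracle_revcomp,
    oracle_scan,
)

from motif_landscape.io_formats import GeneSet, revcomp_consensus
from motif_landscape.motif_discovery import (
    Background,
    CandidateSpec,
    discover_motifs,
    estimate_background,
    scan_consensus,
    sig_value,
    word_probability,
)
from motif_landscape.synthetic_data import PlantSpec, plant_motifs, sample_background


def _one_gene(seq: str) -> GeneSet:
    return GeneSet(["g"], {"g": seq}, region_length=len(seq))


# --- scanning ---------------------------------------------------------------

def test_forward_match_distance_convention():
    # ACGCGT ending 150 bp from the right end → distance 150
    seq = "T" * 44 + "ACGCGT" + "T" * 149
    gs = _one_gene(seq)
    assert scan_consensus("ACGCGT", gs) == [("g", 150, "+")]


def test_reverse_strand_match_only_with_both_strands():
    # plant the reverse complement of a non-palindromic consensus
    consensus = "ACGCGA"
    seq = "T" * 10 + oracle_revcomp(consensus) + "T" * 10
    gs = _one_gene(seq)
    assert scan_consensus(consensus, gs, both_strands=False) == []
    (hit,) = scan_consensus(consensus, gs, both_strands=True)
    assert hit[2] == "-"


def test_palindromic_site_reported_once():
    seq = "T" * 20 + "ACGCGT" + "T" * 20
    hits = scan_consensus("ACGCGT", _one_gene(seq), both_strands=True)
    assert len(hits) == 1 and hits[0][2] == "+"


def test_bipartite_consensus_matches_planted_instance():
    # AYT + 8 Ns + CGT: verify against the independent scanner
    consensus = "AYTNNNNNNNNCGT"
    seq = "G" * 30 + "ACT" + "GTCATTCA" + "CGT" + "G" * 30
    gs = _one_gene(seq)
    hits = scan_consensus(consensus, gs)
    assert hits == oracle_scan(consensus, gs)
    assert len(hits) == 1


def test_sequence_n_never_matched_by_any_symbol():
    gs = _one_gene("AANAA")
    # consensus N admits A/C/G/T but a masked (N) base matches no symbol:
    # the middle position (distance 3) never appears
    hits = scan_consensus("N", gs, both_strands=False)
    assert sorted(d for _, d, _ in hits) == [1, 2, 4, 5]
    assert sorted(d for _, d, _ in scan_consensus("A", gs, both_strands=False)) == [1, 2, 4, 5]


def test_scan_rejects_invalid_symbol(tiny_gene_set):
    with pytest.raises(Exception, match="IUPAC"):
        scan_consensus("ACX", tiny_gene_set)


@pytest.mark.parametrize("consensus", ["ACGCGT", "WSKAA", "AYTNNNNNNNNCGT", "RRR"])
def test_scan_agrees_with_brute_force_oracle(consensus):
    genes = sample_background(6, 120, seed=5)
    assert sorted(scan_consensus(consensus, genes)) == sorted(oracle_scan(consensus, genes))


# --- probabilities and significance ----------------------------------------

def test_word_probability_order0():
    bg = Background()
    assert word_probability("N", bg) == pytest.approx(1.0)
    assert word_probability("A", bg) == pytest.approx(0.25)
    assert word_probability("WS", bg) == pytest.approx(0.25)
    skew = Background(base_freqs=np.array([0.4, 0.1, 0.1, 0.4]))
    assert word_probability("W", skew) == pytest.approx(0.8)


def test_word_probability_order1_matches_enumeration():
    rng = np.random.default_rng(3)
    trans = rng.dirichlet(np.ones(4), size=4)
    pi = rng.dirichlet(np.ones(4))
    bg = Background(order=1, base_freqs=pi, transitions=trans)
    bases = "ACGT"
    for consensus in ["AC", "WS", "RNY"]:
        total = 0.0
        # enumerate every concrete word admitted by the consensus
        def words(prefix, rest):
            if not rest:
                yield prefix
                return
            for b in ORACLE_IUPAC[rest[0]]:
                yield from words(prefix + b, rest[1:])

        for w in words("", consensus):
            p = pi[bases.index(w[0])]
            for a, b in zip(w, w[1:]):
                p *= trans[bases.index(a), bases.index(b)]
            total += p
        assert word_probability(consensus, bg) == pytest.approx(total, rel=1e-12)


def test_sig_value_closed_forms_and_oracle():
    assert sig_value(0, 100, 0.1, 5) == 0.0
    # all successes: P = p^n exactly
    assert sig_value(10, 10, 0.1, 1) == pytest.approx(10.0, rel=1e-9)
    # exact tail-sum oracle
    expected = -(oracle_log10_binom_tail(5, 100, 0.01) + math.log10(1000))
    expected = max(0.0, expected)
    assert sig_value(5, 100, 0.01, 1000) == pytest.approx(expected, rel=1e-9)


def test_sig_value_monotone_in_count():
    sigs = [sig_value(k, 5000, 0.001, 50) for k in range(0, 30)]
    assert all(b >= a for a, b in zip(sigs, sigs[1:]))


def test_sig_value_input_validation():
    with pytest.raises(ValueError):
        sig_value(11, 10, 0.1, 1)
    with pytest.raises(ValueError):
        sig_value(1, 10, 0.0, 1)


# --- discovery --------------------------------------------------------------

PLANTED = "ACGCGTAC"


def _planted_fixture(seed: int, n_genes: int = 20):
    genes = sample_background(n_genes, 800, seed=seed)
    return plant_motifs(
        genes, [PlantSpec("A", n_genes, PLANTED, occurrences_per_gene=1)], seed=seed
    )


def _is_recovery(consensus: str) -> bool:
    """Planted word, its reverse complement, or a same-width IUPAC
    generalization of either (both orientations are scanned)."""
    for ref in (PLANTED, oracle_revcomp(PLANTED)):
        if len(consensus) == len(ref) and all(
            r in ORACLE_IUPAC[c] for c, r in zip(consensus, ref)
        ):
            return True
    return False


def test_planted_motif_recovered_at_rank_one():
    genes, _ = _planted_fixture(seed=42)
    rows = discover_motifs(genes, CandidateSpec(), top_m=5)
    assert rows, "no motifs reported on a planted fixture"
    assert _is_recovery(rows[0].consensus), rows[0].consensus
    assert rows[0].coverage >= 0.9


def test_reported_counts_and_coverage_match_independent_scan():
    genes, _ = _planted_fixture(seed=7, n_genes=10)
    rows = discover_motifs(genes, CandidateSpec(), top_m=10)
    for row in rows:
        oracle = oracle_scan(row.consensus, genes)
        assert row.count == len(oracle) == len(row.occurrences)
        assert row.coverage == pytest.approx(
            len({g for g, _, _ in oracle}) / len(genes)
        )


def test_discovery_is_deterministic(tmp_path):
    genes, _ = _planted_fixture(seed=9, n_genes=8)
    from motif_landscape.io_formats import write_motif_report

    outs = []
    for name in ("a.tsv", "b.tsv"):
        rows = discover_motifs(genes, CandidateSpec(), top_m=15)
        write_motif_report(rows, tmp_path / name)
        outs.append((tmp_path / name).read_bytes())
    assert outs[0] == outs[1]


def test_duplicate_consensus_appears_once():
    genes, _ = _planted_fixture(seed=13, n_genes=8)
    rows = discover_motifs(genes, CandidateSpec(), top_m=25)
    consensi = [r.consensus for r in rows]
    assert len(consensi) == len(set(consensi))


def test_candidate_count_recorded():
    genes, _ = _planted_fixture(seed=3, n_genes=6)
    spec = CandidateSpec()
    discover_motifs(genes, spec, top_m=5)
    assert spec.max_candidates_scored is not None and spec.max_candidates_scored > 0


def test_discovery_rejects_tiny_input():
    gs = GeneSet(["g"], {"g": "ACGT" * 50}, 200)
    with pytest.raises(ValueError):
        discover_motifs(gs, CandidateSpec())


def test_background_estimation_sums_to_one():
    genes = sample_background(5, 200, seed=1)
    for order in (0, 1):
        bg = estimate_background(genes, order=order)
        assert bg.base_freqs.sum() == pytest.approx(1.0)
        if order == 1:
            assert np.allclose(bg.transitions.sum(axis=1), 1.0)


def test_revcomp_consensus_matches_oracle():
    for c in ["ACGCGT", "AYTNNNNNNNNCGT", "WSKM"]:
        assert revcomp_consensus(c) == oracle_revcomp(c)
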