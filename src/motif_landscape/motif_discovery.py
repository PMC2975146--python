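"""Consensus-motif discovery in upstream regions.

Candidate motifs of three kinds are enumerated and scored against a Markov
background:

* **exact** words (e.g. ``ACGCGT``) of length ``k_min``..``k_max`` actually
  present in the sequences;
* **degenerate** IUPAC words (e.g. ``ASTBKG``-style) obtained by generalizing
  over-represented exact words with up to ``max_degenerate_positions``
  two-fold symbols;
* **bipartite** words (e.g. ``AYTNNNNNNNNCGT``) built from pairs of
  over-represented short half-sites separated by an unconstrained gap.

Each candidate's score is its *Sig value*,

    Sig = -log10( min(1, C * P[X >= count]) ),  X ~ Binomial(n_positions, p0)

where ``p0`` is the per-position probability that the background emits a
string matching the consensus, ``n_positions`` is the number of scannable
windows (doubled when both strands are searched and the consensus is not its
own reverse complement) and ``C`` is the number of candidates actually
scored, a Bonferroni-style multiple-testing denominator.  When the same
consensus arises from more than one candidate kind the maximum Sig is kept,
mirroring the max-rule used by ensemble motif finders.

Strand convention: a window matching the consensus on the forward strand is
reported with strand ``+``; a window matching only the reverse complement is
reported with strand ``-``.  A window matching both orientations (always the
case for palindromic consensi such as ``ACGCGT``) is reported once, as ``+``.
The occurrence *distance* is the 1-based upstream distance of the motif base
closest to the gene start (sequences store the gene start at their right
end).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .io_formats import (
    BASES,
    IUPAC,
    GeneSet,
    MotifReportRow,
    revcomp,
    revcomp_consensus,
    validate_consensus,
)

__all__ = [
    "CandidateSpec",
    "Background",
    "estimate_background",
    "scan_consensus",
    "word_probability",
    "sig_value",
    "discover_motifs",
]

_LN10 = math.log(10.0)

# Two-fold degenerate symbols admitting each base; used when generalizing
# exact seed words.
_TWOFOLD_FOR_BASE = {
    "A": ("R", "W", "M"),
    "C": ("Y", "S", "M"),
    "G": ("R", "S", "K"),
    "T": ("Y", "W", "K"),
}


@dataclass
class CandidateSpec:
    """Candidate enumeration parameters.

    ``max_candidates_scored`` is the Bonferroni denominator C; it is set by
    :func:`discover_motifs` to the number of distinct candidates actually
    scored in the run and recorded in the report header.
    """

    kinds: tuple[str, ...] = ("exact", "degenerate", "bipartite")
    k_min: int = 5
    k_max: int = 8
    max_degenerate_positions: int = 3
    gap_min: int = 4
    gap_max: int = 10
    half_len_min: int = 3
    half_len_max: int = 5
    # seeding knobs bounding the combinatorial candidate space
    degenerate_seed_pvalue: float = 1e-7
    max_degenerate_seeds: int = 20
    bipartite_half_seeds: int = 10
    both_strands: bool = True
    max_candidates_scored: int | None = None

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min > k_max")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min > gap_max")
        unknown = set(self.kinds) - {"exact", "degenerate", "bipartite"}
        if unknown:
            raise ValueError(f"unknown candidate kinds {sorted(unknown)}")


@dataclass
class Background:
    """Order-0 or order-1 Markov null model for upstream sequence.

    ``base_freqs`` is a length-4 vector over A,C,G,T; for order 1,
    ``transitions[i, j]`` is P(next=j | prev=i) with rows summing to 1.
    """

    order: int = 0
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    transitions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("background order must be 0 or 1")
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if abs(self.base_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.order == 1:
            if self.transitions is None:
                raise ValueError("order-1 background requires transitions")
            self.transitions = np.asarray(self.transitions, dtype=float)
            if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("transition rows must sum to 1")


def estimate_background(genes: GeneSet, order: int = 0) -> Background:
    """Estimate a background from the gene set's own sequences.

    N bases are skipped; order-1 transitions use add-one smoothing so no
    context has zero mass.
    """
    base_counts = Counter()
    trans_counts = np.ones((4, 4))  # Laplace smoothing
    idx = {b: i for i, b in enumerate(BASES)}
    for g in genes.genes:
        seq = genes.upstream[g]
        prev = None
        for ch in seq:
            if ch == "N":
                prev = None
                continue
            base_counts[ch] += 1
            if prev is not None:
                trans_counts[idx[prev], idx[ch]] += 1
            prev = ch
    total = sum(base_counts.values())
    if total == 0:
        freqs = np.full(4, 0.25)
    else:
        freqs = np.array([base_counts[b] / total for b in BASES])
        # guard against degenerate compositions
        freqs = (freqs + 1e-6) / (freqs + 1e-6).sum()
    if order == 0:
        return Background(order=0, base_freqs=freqs)
    trans = trans_counts / trans_counts.sum(axis=1, keepdims=True)
    return Background(order=1, base_freqs=freqs, transitions=trans)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_matches(seq: str, consensus: str) -> list[int]:
    """Start indices of windows of ``seq`` matching ``consensus`` exactly."""
    w = len(consensus)
    sets = [IUPAC[c] for c in consensus]
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if all(ch in s for ch, s in zip(window, sets)):
            out.append(i)
    return out


def scan_consensus(
    consensus: str, genes: GeneSet, both_strands: bool = True
) -> list[tuple[str, int, str]]:
    """All occurrences of an IUPAC consensus in a gene set.

    Returns (gene-id, upstream distance, strand) triples; overlapping
    occurrences are all reported.  With ``both_strands``, windows matching
    the reverse complement are reported with strand ``-``; a window matching
    both orientations is reported once, as ``+``.
    """
    validate_consensus(consensus)
    w = len(consensus)
    rc = revcomp_consensus(consensus)
    occurrences: list[tuple[str, int, str]] = []
    for g in genes.genes:
        seq = genes.upstream[g]
        fwd = _window_matches(seq, consensus)
        hits = [(i, "+") for i in fwd]
        if both_strands and rc != consensus:
            fwd_set = set(fwd)
            hits += [(i, "-") for i in _window_matches(seq, rc) if i not in fwd_set]
        M = len(seq)
        # distance of the base closest to the gene start (right end)
        gene_hits = [(g, M - (i + w - 1), s) for i, s in hits]
        gene_hits.sort(key=lambda t: (t[1], t[2]))
        occurrences.extend(gene_hits)
    return occurrences


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def word_probability(consensus: str, bg: Background) -> float:
    """Probability that the background emits a consensus match at one position.

    Order 0: product over positions of the summed frequencies of the admitted
    bases (``N`` contributes factor 1).  Order 1: the corresponding Markov
    chain sum, computed by dynamic programming over the admitted base sets.
    """
    validate_consensus(consensus)
    idx = {b: i for i, b in enumerate(BASES)}
    admitted = [[idx[b] for b in sorted(IUPAC[c])] for c in consensus]
    if bg.order == 0:
        p = 1.0
        for adm in admitted:
            p *= float(bg.base_freqs[adm].sum())
        return p
    # order-1: v[b] = P(prefix matched, last base = b)
    v = np.zeros(4)
    v[admitted[0]] = bg.base_freqs[admitted[0]]
    for adm in admitted[1:]:
        nxt = v @ bg.transitions  # type: ignore[arg-type]
        v = np.zeros(4)
        v[adm] = nxt[adm]
    return float(v.sum())


def _log10_binom_sf(observed: np.ndarray, n: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """log10 P[X >= observed] for X ~ Binomial(n, p0), elementwise.

    Uses the regularized-beta survival function; entries that underflow are
    recomputed by a log-space tail summation so extreme significances stay
    finite.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    n = np.broadcast_to(np.asarray(n, dtype=float), observed.shape)
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), observed.shape)
    with np.errstate(divide="ignore"):
        out = stats.binom.logsf(observed - 1, n, p0) / _LN10
    out = np.where(observed <= 0, 0.0, out)
    bad = ~np.isfinite(out) & (observed > 0)
    for j in np.flatnonzero(bad):
        out[j] = _log10_tail_sum(int(observed[j]), int(n[j]), float(p0[j]))
    return out


def _log10_tail_sum(k: int, n: int, p0: float, terms: int = 400) -> float:
    # direct log-space summation of the dominant leading tail terms
    if k <= 0:
        return 0.0
    lp, lq = math.log(p0), math.log1p(-p0)
    hi = min(n, k + terms)
    ks = np.arange(k, hi + 1)
    lchoose = np.array(
        [math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1) for x in ks]
    )
    return float(logsumexp(lchoose + ks * lp + (n - ks) * lq)) / _LN10


def sig_value(observed_count: int, n_positions: int, p0: float, n_candidates: int) -> float:
    """Bonferroni-corrected binomial significance on the -log10 scale.

    ``Sig = -log10(min(1, C * P[X >= observed_count]))`` with
    ``X ~ Binomial(n_positions, p0)``; Sig > 0 means significant after
    correcting for ``n_candidates`` scored candidates.
    """
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if observed_count > n_positions:
        raise ValueError(
            f"observed_count {observed_count} exceeds n_positions {n_positions}"
        )
    if not 0.0 < p0 <= 1.0:
        raise ValueError("p0 must be in (0, 1]")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    log10_p = float(_log10_binom_sf(observed_count, n_positions, p0)[0])
    corrected = log10_p + math.log10(n_candidates)
    return max(0.0, -min(0.0, corrected))


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _word_index(
    genes: GeneSet, lengths: set[int]
) -> tuple[dict[int, Counter], dict[int, dict[str, list[tuple[int, int]]]]]:
    """Per-length forward-strand word counts and (gene, start) position lists.

    Windows containing an N are skipped (masked sequence matches nothing).
    """
    counts: dict[int, Counter] = {k: Counter() for k in lengths}
    positions: dict[int, dict[str, list[tuple[int, int]]]] = {k: {} for k in lengths}
    for gi, g in enumerate(genes.genes):
        seq = genes.upstream[g]
        for k in lengths:
            cnt = counts[k]
            pos = positions[k]
            for i in range(len(seq) - k + 1):
                word = seq[i : i + k]
                if "N" in word:
                    continue
                cnt[word] += 1
                pos.setdefault(word, []).append((gi, i))
    return counts, positions


def _expansion(consensus: str) -> list[str]:
    """All exact words matching an IUPAC consensus (product of admitted sets)."""
    return ["".join(t) for t in itertools.product(*(sorted(IUPAC[c]) for c in consensus))]


def _scannable_positions(genes: GeneSet, width: int) -> int:
    return sum(max(0, len(genes.upstream[g]) - width + 1) for g in genes.genes)


@dataclass
class _Candidate:
    consensus: str
    count: int
    n_positions: int
    p0: float


def _count_union(consensus: str, counts: dict[int, Counter]) -> int:
    """Both-strand window count of a (possibly degenerate) ungapped consensus.

    Equals the number of windows matching the consensus or its reverse
    complement, i.e. exactly what :func:`scan_consensus` reports.
    """
    words = set(_expansion(consensus)) | set(_expansion(revcomp_consensus(consensus)))
    cnt = counts[len(consensus)]
    return sum(cnt.get(w, 0) for w in words)


def _make_candidate(
    consensus: str, count: int, genes: GeneSet, bg: Background, both_strands: bool
) -> _Candidate:
    w = len(consensus)
    n_pos = _scannable_positions(genes, w)
    if both_strands and revcomp_consensus(consensus) != consensus:
        n_pos *= 2
    return _Candidate(consensus, count, n_pos, word_probability(consensus, bg))


def _enumerate_exact(
    genes: GeneSet, spec: CandidateSpec, bg: Background, counts: dict[int, Counter]
) -> dict[str, _Candidate]:
    out: dict[str, _Candidate] = {}
    for k in range(spec.k_min, spec.k_max + 1):
        for word in sorted(counts[k]):
            out[word] = _make_candidate(
                word, _count_union(word, counts), genes, bg, spec.both_strands
            )
    return out


def _uncorrected_log10p(cands: dict[str, _Candidate]) -> dict[str, float]:
    keys = sorted(cands)
    obs = np.array([cands[k].count for k in keys], dtype=float)
    n = np.array([cands[k].n_positions for k in keys], dtype=float)
    p0 = np.array([cands[k].p0 for k in keys], dtype=float)
    logs = _log10_binom_sf(obs, n, p0)
    return dict(zip(keys, logs.tolist()))


def _enumerate_degenerate(
    genes: GeneSet,
    spec: CandidateSpec,
    bg: Background,
    counts: dict[int, Counter],
    exact: dict[str, _Candidate],
    exact_log10p: dict[str, float],
) -> dict[str, _Candidate]:
    # seeds: exact words already extreme before correction
    log_thresh = math.log10(spec.degenerate_seed_pvalue)
    seeds = sorted(
        (w for w, lp in exact_log10p.items() if lp <= log_thresh),
        key=lambda w: (exact_log10p[w], w),
    )[: spec.max_degenerate_seeds]
    out: dict[str, _Candidate] = {}
    for seed in seeds:
        w = len(seed)
        for r in range(1, spec.max_degenerate_positions + 1):
            for pos_combo in itertools.combinations(range(w), r):
                for symbols in itertools.product(
                    *(_TWOFOLD_FOR_BASE[seed[p]] for p in pos_combo)
                ):
                    chars = list(seed)
                    for p, s in zip(pos_combo, symbols):
                        chars[p] = s
                    consensus = "".join(chars)
                    if consensus in out:
                        continue
                    out[consensus] = _make_candidate(
                        consensus,
                        _count_union(consensus, counts),
                        genes,
                        bg,
                        spec.both_strands,
                    )
    return out


def _enumerate_bipartite(
    genes: GeneSet,
    spec: CandidateSpec,
    bg: Background,
    counts: dict[int, Counter],
    positions: dict[int, dict[str, list[tuple[int, int]]]],
) -> dict[str, _Candidate]:
    # half-site seeds: the most over-represented short words per length
    half_cands: dict[str, _Candidate] = {}
    for k in range(spec.half_len_min, spec.half_len_max + 1):
        for word in counts[k]:
            half_cands[word] = _make_candidate(
                word, _count_union(word, counts), genes, bg, spec.both_strands
            )
    half_log10p = _uncorrected_log10p(half_cands) if half_cands else {}
    seeds: list[str] = []
    for k in range(spec.half_len_min, spec.half_len_max + 1):
        words = sorted(
            (w for w in counts[k]),
            key=lambda w: (half_log10p[w], w),
        )[: spec.bipartite_half_seeds]
        seeds.extend(words)

    pos_sets = {
        k: {w: set(v) for w, v in positions[k].items()}
        for k in range(spec.half_len_min, spec.half_len_max + 1)
    }

    def _pattern_windows(left: str, right: str, gap: int) -> set[tuple[int, int]]:
        offset = len(left) + gap
        left_pos = positions[len(left)].get(left, [])
        right_set = pos_sets[len(right)].get(right, set())
        return {(g, i) for g, i in left_pos if (g, i + offset) in right_set}

    out: dict[str, _Candidate] = {}
    for left in seeds:
        for right in seeds:
            for gap in range(spec.gap_min, spec.gap_max + 1):
                consensus = left + "N" * gap + right
                if consensus in out:
                    continue
                windows = _pattern_windows(left, right, gap)
                rc = revcomp_consensus(consensus)
                if spec.both_strands and rc != consensus:
                    windows = windows | _pattern_windows(
                        revcomp(right), revcomp(left), gap
                    )
                out[consensus] = _make_candidate(
                    consensus, len(windows), genes, bg, spec.both_strands
                )
    return out


# ---------------------------------------------------------------------------
# Discovery driver
# ---------------------------------------------------------------------------

def discover_motifs(
    genes: GeneSet,
    spec: CandidateSpec | None = None,
    bg: Background | None = None,
    top_m: int = 25,
    min_sig: float = 0.0,
) -> list[MotifReportRow]:
    """Discover significant consensus motifs in a gene set.

    Candidates of all configured kinds are scored by :func:`sig_value` with
    C = the number of distinct candidates scored; the top ``top_m`` consensi
    with Sig >= ``min_sig`` are returned, sorted by Sig descending then
    consensus lexicographically, with occurrences from :func:`scan_consensus`.
    The run's C is stored on ``spec.max_candidates_scored``.
    """
    if len(genes) < 2:
        raise ValueError("discover_motifs requires at least 2 genes")
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if spec is None:
        spec = CandidateSpec()
    if bg is None:
        bg = estimate_background(genes, order=0)

    lengths = set(range(spec.k_min, spec.k_max + 1))
    if "bipartite" in spec.kinds:
        lengths |= set(range(spec.half_len_min, spec.half_len_max + 1))
    counts, positions = _word_index(genes, lengths)

    candidates: dict[str, _Candidate] = {}

    def _merge(new: dict[str, _Candidate]) -> None:
        # identical consensi score identically here; max-rule keeps one copy
        for consensus, cand in new.items():
            candidates.setdefault(consensus, cand)

    exact: dict[str, _Candidate] = {}
    if "exact" in spec.kinds:
        exact = _enumerate_exact(genes, spec, bg, counts)
        _merge(exact)
    if "degenerate" in spec.kinds:
        if not exact:
            exact = _enumerate_exact(genes, spec, bg, counts)
        exact_log10p = _uncorrected_log10p(exact) if exact else {}
        _merge(
            _enumerate_degenerate(genes, spec, bg, counts, exact, exact_log10p)
        )
    if "bipartite" in spec.kinds:
        _merge(_enumerate_bipartite(genes, spec, bg, counts, positions))

    if not candidates:
        spec.max_candidates_scored = 0
        return []

    C = len(candidates)
    spec.max_candidates_scored = C
    log10_c = math.log10(C)
    keys = sorted(candidates)
    log10p = _log10_binom_sf(
        np.array([candidates[k].count for k in keys], dtype=float),
        np.array([candidates[k].n_positions for k in keys], dtype=float),
        np.array([candidates[k].p0 for k in keys], dtype=float),
    )
    sigs = np.maximum(0.0, -np.minimum(0.0, log10p + log10_c))
    order = sorted(range(len(keys)), key=lambda j: (-sigs[j], keys[j]))

    n_genes = len(genes)
    rows: list[MotifReportRow] = []
    for j in order:
        if sigs[j] < min_sig:
            break  # sorted descending; nothing further qualifies
        consensus = keys[j]
        occurrences = scan_consensus(consensus, genes, spec.both_strands)
        assert len(occurrences) == candidates[consensus].count, consensus
        coverage = len({g for g, _, _ in occurrences}) / n_genes
        rows.append(
            MotifReportRow(
                consensus=consensus,
                count=len(occurrences),
                sig=float(sigs[j]),
                coverage=coverage,
                occurrences=occurrences,
            )
        )
        if len(rows) >= top_m:
            break
    return rows
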