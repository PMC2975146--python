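"""Readers and writers for every on-disk representation the pipeline touches.

Formats handled here:

* FASTA upstream sequences (one record per gene, 5'→3' on the coding strand
  with the gene start at the right end of the sequence);
* tab-delimited motif reports (consensus, count, Sig, coverage, occurrence
  list), the same schema a SCOPE-style motif finder exports;
* two-column gene→category annotation TSV;
* motif databases, either minimal MEME format or a two-column
  name/IUPAC-consensus TSV.

Readers never silently repair data: every invariant violation raises
:class:`FormatError` with enough location information to find the offending
line.  Coordinates throughout are *upstream distances*: 1-based bp from the
gene start, measured at the motif base closest to the start, so distance 1
is immediately adjacent to the start and distance L is the far end of the
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "IUPAC",
    "IUPAC_COMPLEMENT",
    "FormatError",
    "GeneSet",
    "MotifReportRow",
    "revcomp",
    "revcomp_consensus",
    "read_gene_set",
    "write_gene_set",
    "write_motif_report",
    "read_motif_report",
    "read_motif_report_metadata",
    "read_annotation",
    "write_annotation",
    "read_motif_db",
    "write_motif_db",
]

#: IUPAC nucleotide codes mapped to the set of plain bases each admits.
#: ``N`` in a *sequence* is masked genomic material and is matched by no
#: consensus symbol, including consensus ``N``.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

BASES = "ACGT"
_SEQ_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated its format contract; the message names the location."""


def revcomp(seq: str) -> str:
    """Reverse complement of a plain DNA string (N stays N)."""
    return seq.translate(_DNA_TRANS)[::-1]


_DNA_TRANS = str.maketrans("ACGTN", "TGCAN")


def revcomp_consensus(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus string."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(consensus))
    except KeyError as exc:
        raise FormatError(f"invalid IUPAC symbol {exc.args[0]!r} in consensus {consensus!r}")


def validate_consensus(consensus: str) -> str:
    if not consensus:
        raise FormatError("empty consensus")
    bad = [c for c in consensus if c not in IUPAC]
    if bad:
        raise FormatError(f"invalid IUPAC symbol {bad[0]!r} in consensus {consensus!r}")
    return consensus


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """An ordered set of genes with their upstream regions.

    Parameters
    ----------
    genes:
        Gene identifiers in input order; unique, non-empty.
    upstream:
        Map gene id → DNA string over {A,C,G,T,N}, 5'→3' on the coding
        strand with the gene start at the right end.
    region_length:
        The nominal upstream window length L in bp (default 800, the
        community standard for *S. cerevisiae*).  Individual sequences may
        be shorter, never longer.
    """

    genes: list[str]
    upstream: dict[str, str]
    region_length: int = 800

    def __post_init__(self) -> None:
        if self.region_length < 1:
            raise ValueError("region_length must be >= 1")
        seen: set[str] = set()
        for g in self.genes:
            if not g:
                raise ValueError("empty gene id")
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r}")
            seen.add(g)
        if seen != set(self.upstream):
            raise ValueError("genes and upstream keys disagree")
        for g, seq in self.upstream.items():
            if len(seq) > self.region_length:
                raise ValueError(
                    f"sequence for {g!r} is {len(seq)} bp, longer than region_length "
                    f"{self.region_length} (pre-trim upstream regions)"
                )
            for pos, ch in enumerate(seq):
                if ch not in _SEQ_ALPHABET:
                    raise ValueError(
                        f"non-ACGTN character {ch!r} at position {pos + 1} of {g!r}"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        """A new GeneSet restricted to ``gene_ids``, preserving this order."""
        keep = set(gene_ids)
        missing = keep - set(self.genes)
        if missing:
            raise KeyError(f"genes not in set: {sorted(missing)}")
        genes = [g for g in self.genes if g in keep]
        return GeneSet(genes, {g: self.upstream[g] for g in genes}, self.region_length)


def read_gene_set(fasta_path: str | Path, region_length: int = 800) -> GeneSet:
    """Read upstream sequences from FASTA into a :class:`GeneSet`.

    Ids are the first whitespace token of each header, taken verbatim;
    sequences are uppercased.  Duplicate ids, sequences longer than
    ``region_length`` and non-ACGTN characters are hard errors.
    """
    genes: list[str] = []
    upstream: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gid = record.id
        if gid in upstream:
            raise FormatError(f"{fasta_path}: duplicate record id {gid!r}")
        genes.append(gid)
        upstream[gid] = str(record.seq).upper()
    try:
        return GeneSet(genes, upstream, region_length)
    except ValueError as exc:
        raise FormatError(f"{fasta_path}: {exc}") from exc


def write_gene_set(genes: GeneSet, fasta_path: str | Path) -> None:
    with open(fasta_path, "w", newline="\n") as fh:
        for g in genes.genes:
            fh.write(f">{g}\n{genes.upstream[g]}\n")


# ---------------------------------------------------------------------------
# Motif reports
# ---------------------------------------------------------------------------

@dataclass
class MotifReportRow:
    """One discovered motif, in the tab-delimited report schema.

    ``occurrences`` holds (gene-id, upstream distance in bp, strand) triples;
    ``count`` equals ``len(occurrences)`` and ``coverage`` is the fraction of
    the parent gene set's genes with at least one occurrence.
    """

    consensus: str
    count: int
    sig: float
    coverage: float
    occurrences: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_consensus(self.consensus)
        if self.count != len(self.occurrences):
            raise ValueError(
                f"{self.consensus}: count {self.count} != {len(self.occurrences)} occurrences"
            )
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"{self.consensus}: coverage {self.coverage} outside [0,1]")
        for gene, dist, strand in self.occurrences:
            if dist < 1:
                raise ValueError(f"{self.consensus}: upstream distance {dist} < 1")
            if strand not in ("+", "-"):
                raise ValueError(f"{self.consensus}: bad strand {strand!r}")

    def genes_covered(self) -> set[str]:
        return {g for g, _, _ in self.occurrences}


_REPORT_COLUMNS = ["consensus", "count", "sig", "coverage", "occurrences"]


def _fmt6(x: float) -> str:
    return f"{x:.6g}"


def write_motif_report(
    rows: Iterable[MotifReportRow],
    path: str | Path,
    *,
    region_length: int | None = None,
    n_candidates_scored: int | None = None,
) -> None:
    """Write rows as a tab-delimited report.

    Floats carry 6 significant digits; occurrences are semicolon-joined
    ``gene:distance:strand`` triples.  Optional metadata (region length, the
    multiple-testing denominator C) goes into ``# key=value`` header lines.
    """
    with open(path, "w", newline="\n") as fh:
        if region_length is not None:
            fh.write(f"# region_length={region_length}\n")
        if n_candidates_scored is not None:
            fh.write(f"# n_candidates_scored={n_candidates_scored}\n")
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in rows:
            occ = ";".join(f"{g}:{d}:{s}" for g, d, s in row.occurrences)
            fh.write(
                f"{row.consensus}\t{row.count}\t{_fmt6(row.sig)}\t{_fmt6(row.coverage)}\t{occ}\n"
            )


def read_motif_report(
    path: str | Path, *, region_length: int | None = None
) -> list[MotifReportRow]:
    """Read a tab-delimited motif report back into rows.

    Distances are validated against ``region_length`` (argument, or the
    ``# region_length=`` header if present); malformed occurrence triples
    raise with the line number.
    """
    rows: list[MotifReportRow] = []
    meta = read_motif_report_metadata(path)
    if region_length is None and "region_length" in meta:
        region_length = int(meta["region_length"])
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line.split("\t") != _REPORT_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: bad header {line!r}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            consensus, count_s, sig_s, cov_s, occ_s = parts
            occurrences: list[tuple[str, int, str]] = []
            if occ_s:
                for triple in occ_s.split(";"):
                    bits = triple.rsplit(":", 2)
                    if len(bits) != 3 or bits[2] not in ("+", "-"):
                        raise FormatError(
                            f"{path}:{lineno}: malformed occurrence triple {triple!r}"
                        )
                    try:
                        dist = int(bits[1])
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-integer distance in {triple!r}"
                        ) from None
                    if region_length is not None and not 1 <= dist <= region_length:
                        raise FormatError(
                            f"{path}:{lineno}: distance {dist} outside [1, {region_length}]"
                        )
                    occurrences.append((bits[0], dist, bits[2]))
            try:
                rows.append(
                    MotifReportRow(
                        consensus=consensus,
                        count=int(count_s),
                        sig=float(sig_s),
                        coverage=float(cov_s),
                        occurrences=occurrences,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if not header_seen:
            raise FormatError(f"{path}: missing header line")
    return rows


def read_motif_report_metadata(path: str | Path) -> dict[str, str]:
    """Parse leading ``# key=value`` lines of a motif report."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation(tsv_path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>category table into gene → {categories}.

    Repeated pairs are deduplicated.  Genes absent from the file simply do
    not appear as keys (callers treat a missing gene as the empty set).
    """
    mapping: dict[str, set[str]] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{tsv_path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            gene, category = parts
            mapping.setdefault(gene, set()).add(category)
    return mapping


def write_annotation(mapping: Mapping[str, Iterable[str]], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="\n") as fh:
        for gene in sorted(mapping):
            for category in sorted(set(mapping[gene])):
                fh.write(f"{gene}\t{category}\n")


# ---------------------------------------------------------------------------
# Motif databases (known binding sites)
# ---------------------------------------------------------------------------

def read_motif_db(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a motif database into ``[(name, PWM)]``.

    Accepts minimal MEME format (detected by a leading ``MEME version``
    line) or a two-column TSV of name and IUPAC consensus, converted to a
    PWM with the standard pseudo-probability rule.  PWMs are (width, 4)
    arrays over A,C,G,T; every column must sum to 1 within 1e-9 and names
    must be unique.
    """
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("MEME version"):
        entries = _parse_meme(text, str(path))
    else:
        entries = _parse_consensus_tsv(text, str(path))
    names = [n for n, _ in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate motif name(s) {sorted(dupes)}")
    for name, pwm in entries:
        if pwm.shape[0] == 0:
            raise FormatError(f"{path}: zero-width motif {name!r}")
        sums = pwm.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"{path}: motif {name!r} column {bad + 1} sums to {sums[bad]:.6g}, not 1"
            )
        if np.any(pwm < 0):
            raise FormatError(f"{path}: motif {name!r} has negative entries")
    return entries


def _parse_meme(text: str, where: str) -> list[tuple[str, np.ndarray]]:
    # Minimal MEME format: "MOTIF <name>" then a "letter-probability matrix:"
    # header followed by w rows of 4 probabilities.  Parsed directly so the
    # probabilities are taken verbatim (no pseudo-count rounding).
    entries: list[tuple[str, np.ndarray]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{where}:{i + 1}: MOTIF line without a name")
            name = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{where}: motif {name!r} has no probability matrix")
                i += 1
            if i == len(lines):
                raise FormatError(f"{where}: motif {name!r} has no probability matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = stripped.split()
                if len(vals) != 4:
                    raise FormatError(
                        f"{where}:{i + 1}: expected 4 probabilities, got {len(vals)}"
                    )
                rows.append([float(v) for v in vals])
                i += 1
            entries.append((name, np.array(rows, dtype=float).reshape(len(rows), 4)))
        else:
            i += 1
    return entries


def _parse_consensus_tsv(text: str, where: str) -> list[tuple[str, np.ndarray]]:
    # Deferred import: motif_matching owns the consensus→PWM rule.
    from .motif_matching import consensus_to_pwm

    entries: list[tuple[str, np.ndarray]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{where}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        name, consensus = parts
        try:
            pwm = consensus_to_pwm(consensus)
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{where}:{lineno}: {exc}") from exc
        entries.append((name, pwm))
    return entries


def write_motif_db(entries: Iterable[tuple[str, np.ndarray]], path: str | Path) -> None:
    """Write ``[(name, PWM)]`` in minimal MEME format."""
    with open(path, "w", newline="\n") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pwm in entries:
            pwm = np.asarray(pwm, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.shape[0]} nsites= 20\n"
            )
            for row in pwm:
                # full float precision so read(write(x)) reproduces x exactly
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")
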