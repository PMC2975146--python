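# Methods

## Problem and overall model

The package subdivides a co-expressed gene set using only upstream sequence
evidence: the identity of over-represented motifs and their positional
distribution relative to the gene start. The working assumption is that a
transcription factor's sites concentrate at a characteristic distance from
the start, so genes regulated by different factors separate even when the
factors' motifs share a sequence core. All coordinates are *upstream
distances*: 1-based bp from the gene start, measured at the motif base
closest to the start. Upstream FASTA records are stored 5'→3' on the coding
strand with the gene start at the right end; this is the only place the
orientation convention is enforced.

## Motif discovery

Three candidate classes are enumerated:

* **exact** words of length 5–8 actually present in the sequences;
* **degenerate** words: exact words whose uncorrected binomial p-value falls
  below 1e-7 (at most 20 seeds) are generalized with up to three two-fold
  IUPAC symbols at any positions. Full degenerate enumeration is
  combinatorially explosive; seeding from already-extreme exact words bounds
  the candidate count while still producing the degenerate shapes seen in
  real regulons. The seed threshold is deliberately strict: on pure
  background the chance that any seed exists is < 1%, so the post-hoc
  variant search cannot inflate the family-wise false-positive rate it is
  not corrected for.
* **bipartite** words: pairs of 3–5 bp half-sites separated by a fixed gap
  of 4–10 Ns; half-sites are the 10 most over-represented words per length.

Every candidate is scored by `Sig = -log10(min(1, C·P[X ≥ x]))` with
`X ~ Binomial(n, p0)`: `x` is the number of matching windows, `n` the number
of scannable windows (doubled when both strands are searched and the
consensus is not its own reverse complement), `p0` the background match
probability (product of admitted-base frequencies for order 0; a dynamic
program over admitted base sets for order 1), and `C` the number of distinct
candidates scored, recorded in the report header. When the same consensus
arises from several classes the maximum Sig is kept (an ensemble max-rule;
under this unified scoring duplicates tie, so the rule reduces to
deduplication). Ties in the final ranking break lexicographically, making
reports byte-deterministic.

Strand handling: a window matching the consensus forward is reported `+`; a
window matching only the reverse complement is `-`; a window matching both
(always true for palindromes such as ACGCGT) is reported once, as `+`. The
binomial model ignores the small probability that a non-palindromic
consensus and its reverse complement match the same window, which makes Sig
slightly conservative in that rare case.

The exact binomial tail is evaluated through the regularized-beta survival
function; entries that underflow double precision are recomputed by
log-space summation of the leading 400 tail terms (the tail is dominated by
its first terms whenever underflow occurs).

## Quartile profiles

The upstream window L (default 800 bp, divisible by the bin count) is cut
into B equal bins (default 4 × 200 bp). Bins are half-open on the left,
(0,200], (200,400], …, so distance d falls in bin ⌈d/width⌉ — the simplest
total assignment for 1-based distances. Each gene's profile is its
per-(motif, bin) occurrence count vector, raw counts by default (an optional
L2 normalization exists but is off: occurrence *numbers* carry evidence at
these scales). Genes with all-zero profiles are kept and later labelled
`unclustered` rather than dropped, so coverage accounting stays honest.
Only motifs with Sig ≥ 2 enter the pipeline's profiles by default; at
Sig ≥ 0 the report fills with family-wise-insignificant words whose counts
add noise columns to the clustering substrate.

## Landscape clustering

The gene-motif vectors are clustered in the style of force-directed
knowledge-mapping tools, automated end to end:

1. **Similarity graph**: mutualized k-nearest-neighbour graph (default
   k = 10) under cosine distance (zero vectors at distance 1 by convention);
   edge weight = 1 − distance/max-distance ∈ [0, 1].
2. **Layout**: nodes start at positions hashed from (seed, gene id) — this
   keys the result to gene identity, making labels invariant to input
   order, something interactive layout tools cannot offer. Per iteration
   each node feels linear spring attraction along edges (weight × distance,
   scale 0.2) and inverse-distance pairwise repulsion (scale 0.002, with
   distances floored at 0.01 so coincident points exert bounded force); the
   step is capped by a temperature that starts at 0.1 and cools
   geometrically (γ = 0.97). Iteration stops when the largest displacement
   drops below 1e-3 × the plane diagonal ("no more movement") or after
   2000 iterations; in practice quiescence arrives after ~100–130
   iterations. The slower-than-usual cooling gives disconnected blobs
   enough total travel (≈ T₀/(1−γ)) to separate cleanly before freezing.
3. **Terrain**: Gaussian kernel density on a 96×96 grid padded by three
   bandwidths; each kernel carries unit mass so the grid integrates to the
   gene count. The default bandwidth is *half* of Scott's 2-D rule —
   Scott's rule targets unimodal densities and oversmooths a landscape
   whose whole point is its separate peaks — floored at the layout's
   spring/repulsion equilibrium spacing (repulsion/attraction)^(1/3),
   because the layout cannot bring even identical profiles closer than
   that; the floor only binds at very small n.
4. **Peaks and basins**: local maxima are filtered by topographic
   prominence (union-find persistence over cells in descending height;
   default threshold 0.1 × the global maximum), replacing the visual peak
   selection of interactive tools with a single reproducible knob. Genes
   follow a discrete steepest ascent from their nearest grid cell; genes
   whose ascent ends at a sub-threshold maximum, and all-zero-profile
   genes, are labelled `unclustered`. No cluster count is ever specified.

## Enrichment

Each subset is tested against a universe — by default the starting gene
set, not the genome, because the question is whether a subset is more
coherent than the set it came from (a genome-style universe can be supplied
instead). Per category: hypergeometric upper tail computed in log-space
(lgamma + logsumexp), BH-corrected across categories, significance gate
q < 0.05. Categories overlapping a single subset gene are reported but
flagged rather than filtered. Relative to the parent set a subset category
is *new* (significant only in the subset), *improved* (significant in both
with p smaller by ≥ 100×, matching the order-of-magnitude gains that
motivate subclustering), *unchanged*, or *absent*. With the default
universe the parent's self-enrichment is degenerate (all p = 1), so
categories surface as *new*; *improved* becomes informative when a larger
universe is supplied.

## Motif matching

Discovered consensi become PWMs (admitted bases share 1 − pseudo·k_off
equally, disallowed bases get pseudo = 0.01 each, N is uniform) and are
aligned to each database PWM over all offsets and both orientations with
overlap ≥ 4 (shorter overlaps produce spurious zero-distance matches).
Score = mean per-column Euclidean distance; ties prefer larger overlap,
then smaller |offset|, then `+`. Because this score has no analytic null,
each target gets an empirical E-value: the observed score is ranked among
500 seeded column-shuffle decoys of that target,
`E = (1 + #{null ≤ observed}) / 501 × db_size`. The resolution floor is
therefore ≈ 0.002 × db_size, and column-shuffle ties place even perfect
matches of repetitive (e.g. CGCG-core) motifs at empirical p ≈ 0.02–0.05;
the default reporting threshold is 0.05 × db_size — the conventional
significance level for a rank-based p-value — anything stricter would
discard correct matches of exactly the low-complexity motifs this domain
cares about. E-values are comparable within a database, not across
databases or to analytic E-values from other tools.

## Pipeline

`run_pipeline` chains the stages and re-analyzes every peak with at least 5
genes (below that, binomial significance is meaningless); smaller subsets
are reported but skipped. Every stage writes its standard file format so
any stage can be rerun standalone; the summary JSON carries a hash of the
configuration (excluding the output directory) and no timestamps, so a
config + seed reproduces every output byte for byte.

## Synthetic fixtures

The generator emulates the pipeline's inputs: i.i.d. or first-order Markov
background upstream regions; motif instances overwritten (not inserted, so
L stays fixed) at positions sampled per-quartile with controlled weights,
non-overlapping within a gene, degenerate symbols resolved uniformly and
reverse-complemented with probability 1 − strand_prob_plus; a private
annotation category per subset (coverage 0.9, 5% leak-through noise, two
background categories at rate 0.3); and a motif database holding the
planted motifs under regulator-style names. Scenario presets: a two-subset
and a three-subset design whose planted 8-bp motifs share the CGCG core but
occupy different quartiles (bins 2 vs 1, and bins 3–4/2/1), 15 genes per
subset, two instances per gene — enough for a subset motif to clear the
family-wise bar when discovery runs on the *pooled* set — and a pure
background null. Planted consensi are 8 bp, the top of the candidate length
range, so the exact word (or its reverse complement, or a generalization of
either) is the analytically best-scoring representation rather than one of
many equivalent flank-extensions; and their self-match shuffle-tie rates
lie below the E-value reporting threshold so the match stage is actually
exercised. Fixture sizes keep the full pipeline in the tens of seconds on
one CPU.

What the fixtures do **not** model: real promoter composition (nucleosome
positioning, TATA statistics, CpG effects), overlapping regulons, motif
cooperativity/spacing constraints beyond fixed-gap bipartite sites, and
annotation structure (no ontology graph, no term propagation). Passing
tests therefore demonstrate the machinery's correctness and calibration
under controlled conditions, not performance on genomic data.

## Known limitations

* Sig treats windows as independent Bernoulli trials; self-overlapping
  words (homopolymers, short repeats) clump and carry a heavier-than-
  binomial tail. The null calibration shows the family-wise contract still
  holds with margin, but per-word p-values for such words are optimistic.
* Degenerate candidates only generalize already-extreme exact words; a
  motif that is invisible at every exact instantiation (high degeneracy,
  low per-word count) will be missed.
* The force layout is a heuristic: topology is reliable (what clusters
  with what), geometry is not (distances between peaks carry no units).
* Empirical E-values are rank statistics with a hard floor; they cannot
  distinguish matches better than ~0.002 × db_size.
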