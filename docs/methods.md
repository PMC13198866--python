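# Methods

## Alignment model

Global (Needleman–Wunsch) alignment of two protein sequences A, B under
an integer substitution matrix and affine gap penalties. A gap of length
k costs `gap_open + k·gap_extend`; the opening charge applies on the
first gap symbol, **including** a direct switch between a gap in A and a
gap in B (a deletion immediately followed by an insertion opens a new
gap). Scores are similarities to be maximised; "cost" parameters from
slider-style interfaces are interpreted as score shortfall. End gaps are
charged like any other gap (no semi-global variant).

The DP lattice has three states per cell: M (last step consumed one
symbol of each sequence), D (inside a gap consuming A, drawn vertically)
and I (inside a gap consuming B, drawn horizontally). Because a vertex's
state is a function of the move that entered it, source→sink lattice
paths are in bijection with alignments: path identity equals alignment
identity, which makes counting well defined.

All DP is exact integer arithmetic; no floats enter any score, count or
threshold comparison.

## The Δ-suboptimal space and its graph

With opt the optimal score and Δ ≥ 0, the suboptimal space is the set of
alignments with score ≥ opt − Δ. The alignment graph retains edge
u→v (weight w) iff `forwardBest(u) + w + backwardBest(v) ≥ opt − Δ`,
with forward/backward best prefix/suffix scores kept per affine state —
i.e. exactly the edges used by at least one Δ-suboptimal alignment.

A subtlety documented here because it shapes the counting design: the
union graph of those edges generically admits *crossover* walks scoring
below opt − Δ (a prefix good for one alignment concatenated with a
suffix good for another). The counted universe is therefore **not**
"all walks of the union graph" but the exact score-thresholded space.

## Exact, score-stratified counting

`count_paths` keeps, for every vertex v, the distribution of prefix
scores as shortfalls from the best prefix score: `forward_dist[v][k]` =
number of source→v prefixes scoring `fbest(v) − k`. Entries that cannot
participate in any admissible full path (k beyond
`fbest(v) + bbest(v) − threshold`) are pruned, which bounds each array
by Δ + 1 entries; the threshold is additionally capped from below by the
worst achievable full-path score, so pathological Δ values (larger than
the score range) cost nothing. Backward distributions are symmetric.
T — the exact number of Δ-suboptimal alignments — is accumulated both
forward and backward and asserted identical.

The number of admissible alignments containing a fixed contiguous
subpath p from u to v with total edge weight W is

    Σ_{k1 + k2 ≤ slack} forward_dist[u][k1] · backward_dist[v][k2],
    slack = fbest(u) + W + bbest(v) − threshold,

evaluated with cumulative sums of the backward distribution. Supports
are this count over T, reduced Fractions of Python big integers. On
instances without crossover walks this collapses to the familiar
`forward(u)·backward(v)/T` product.

## Safety windows

A safety window is a maximal contiguous edge subpath with support ≥ α,
containing at least one edge (single safe vertices project to
zero-length intervals and are not reported). Extraction:

- **α > 1/2 (chain sweep).** Any two subpaths with support above one
  half are contained in a common alignment, so every vertex of an α-safe
  subpath is itself α-safe, the α-safe vertices form a single chain in
  topological order, and consecutive chain members that co-occur in
  windows are joined by a unique edge. Windows are found by a
  two-pointer sweep over each edge-connected chain segment; subpath
  support is monotone non-increasing under extension on either side,
  which is exactly what the sweep requires. Cost: O(chain · Δ) big-int
  operations after counting.
- **α ≤ 1/2 (enumeration fallback).** Safe subpaths need not lie on one
  chain, so extraction enumerates the suboptimal space exhaustively
  (guarded by an input-size bound, default 64 lattice cells) and
  searches maximal safe subpaths directly; a warning signals the
  fallback.

Float α values are interpreted through their decimal representation
(0.6 means exactly 3/5) so threshold comparisons are never subject to
binary rounding. Windows are projected to 0-based half-open intervals
spanned by their endpoint vertices; indel-only windows legitimately
yield a zero-length interval on one sequence and are reported as such.
Human-readable TSV output converts to labelled 1-based inclusive
coordinates; JSON keeps the internal convention and carries T as a
decimal string because counts routinely exceed 2^64.

Reported one-optimal-path output breaks score ties deterministically:
diagonal, then vertical, then horizontal, resolved left to right from
the source.

## Defaults

| parameter | default | why |
|---|---|---|
| matrix | BLOSUM62 | standard general-purpose protein matrix |
| gap_open / gap_extend | 11 / 1 | BLAST-like convention for BLOSUM62 |
| Δ | 0 | suboptimal depth is an explicit analysis choice |
| α | 0.75 | three-quarters majority; strict but not unanimous |

The structure mapper aligns the query to a chain's *observed* polymer
residues (coordinate records, via gemmi) with the IDENTITY matrix
(gap 2/1), maps only identically aligned positions to author residue
numbers, and rejects pairings under 30% identity over aligned columns —
annotations are meant for residues a viewer can actually colour, so
unobserved residues are inherently unmapped.

## Synthetic data and the divergence experiment

The generator draws an ancestor uniformly over the 20 canonical amino
acids and derives a partner by site-wise mutation: substitution with
probability d (uniform over the other 19 residues), insertion/deletion
each with probability d/10 per site (indel rate d/5 split evenly) with
geometric lengths of mean 2. It emulates a divergence axis only: no
rate heterogeneity, no compositional bias, no domain structure, no
back-mutation bookkeeping. Passing trend tests therefore show how
safety behaves as sequence signal decays, not that the model mimics any
particular protein family.

The experiment runs seeded replicates per (length, divergence) cell with
Δ scaled to sequence length (`max(1, 0.2·L)` — deep enough that a
divergent pair opens a rich suboptimal space, shallow enough that an
identical pair keeps an essentially unique optimum) and α = 0.75, and
reports mean safe coverage, window count/length and digits of T. At
length 100 with 30 replicates, mean coverage drops from ≈0.95 at
divergence 0.05 to ≈0.68 at divergence 0.5 — divergent pairs yield
sparser safety windows, while T explodes (mean digits 1.7 → 5.5).
Experiment sizes used in the test suite (length ≤ 100, ≤ 30 replicates)
keep the whole suite in the minutes range; the generator accepts up to
length 200 / 50 replicates.

## Numerical and degenerate-input choices

- Unbounded integers throughout counting; Fractions reduced to lowest
  terms for supports.
- Residues outside the matrix alphabet are rejected at alignment time
  with symbol and position; scores are never invented.
- Empty-vs-empty input yields the single empty alignment (T = 1, no
  windows); one empty sequence yields the forced gap path.
- The brute-force enumerator takes its optimum from the enumeration
  itself, so tests compare two genuinely independent routes.

## Known limitations

- Counting weights all Δ-suboptimal alignments uniformly; no
  partition-function (score-weighted) variant.
- Pairwise only; no multiple-sequence safety.
- No local or semi-global alignment; no banded acceleration beyond the
  Δ pruning itself.
- The α ≤ 1/2 regime is exact but enumeration-bound, hence limited to
  small inputs.
- Rendering is a static export; per-cell aggregation of edge supports is
  per-edge opacity, with overlapping state copies drawn individually.
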