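# alnsafe

**Alignment-safety analysis for pairwise protein alignments.**

A single optimal alignment hides the fact that, especially for divergent
protein pairs, thousands of near-optimal alternatives may exist that are
just as biologically plausible — trusting only the highest-scoring one
introduces a systematic *optimal alignment bias*. `alnsafe` makes the
alternative-alignment space explicit: it computes the set of all global
alignments scoring within a shortfall **Δ** of the optimum, counts them
exactly, and extracts **safety windows** — maximal contiguous alignment
intervals shared by at least an **α** proportion of all those
alignments (α = 1 demands unanimity). Safe intervals are the parts of an
alignment you can rely on regardless of which near-optimal configuration
is the "true" one; everything outside them is alignment-ambiguous.

It is a library plus a command-line tool, intended for anyone doing
pairwise protein comparison who needs to know *which* aligned positions
are robust: comparative modellers, structure mappers, curators of
divergent homolog pairs.

## Method

Needleman–Wunsch global alignment with affine gap penalties
(`gap_open + k·gap_extend` for a gap of length k) over a substitution
matrix s(x, y) (BLOSUM45/50/62/80/90, PAM30/70/250, IDENTITY, or any
NCBI-format matrix file). The three-state dynamic-programming lattice
(match M, gap-in-A D, gap-in-B I) is a DAG whose source→sink paths are in
bijection with global alignments. With opt the optimal score:

- the **Δ-suboptimal space** is every alignment with score ≥ opt − Δ;
- the **alignment graph** keeps exactly the lattice edges used by at
  least one such alignment (decided exactly from best prefix/suffix
  scores, all integer arithmetic);
- **path counting** is exact and score-stratified: T, the number of
  Δ-suboptimal alignments, and the support of any edge or contiguous
  subpath (the fraction of the T alignments containing it) are computed
  as arbitrary-precision integers and exact rationals — never floats;
- a **safety window** is a maximal contiguous subpath with support ≥ α,
  projected back to 0-based half-open intervals on both sequences;
  **safe coverage** is the fraction of each sequence inside windows.

Raising Δ enlarges the suboptimal space (T and the edge set never
shrink); raising α makes the criterion stricter (coverage never grows,
and every higher-α window lies inside a lower-α window). Both behaviours
are asserted by the test suite, along with exact agreement of the whole
pipeline with brute-force enumeration on thousands of small instances.

Results can be rendered as a static alignment graph (SVG/PNG/JPEG:
diagonal = match/mismatch, vertical/horizontal = indel, edge opacity =
support, windows green, optimal path blue, a selected alternative path
orange) and projected onto PDB/mmCIF structure chains as per-residue
annotations.

## Worked example

```sh
cat > pair.fa <<'EOF'
>seqA
HEAGAWGHEE
>seqB
PAWHEAE
EOF
alnsafe safety --fasta pair.fa --matrix BLOSUM50 \
    --gap-open 10 --gap-extend 1 --delta 5 --alpha 0.75 -o out
```

prints (stderr):

```
opt_score=8 num_alignments=4 windows=1 coverage_a=0.1000 coverage_b=0.1429
```

meaning: the optimal BLOSUM50 score is 8, there are T = 4 alignments
within Δ = 5 of it, and exactly one interval is shared by at least 3/4 of
them. `out/windows.tsv` shows it (coordinates 1-based inclusive):

```
a_start_1based	a_end_1based	b_start_1based	b_end_1based	support	support_exact
6	6	3	3	1.000000	1/1
```

— the aligned tryptophans (A position 6, B position 3) are the only
alignment-safe residue pair: all 4 suboptimal alignments agree on it
(support 1/1), while the rest of the optimal alignment

```
HEAGAWGHEE
P---AWHEAE
```

is ambiguous at this depth of the suboptimal space. `out/result.json`
carries the full machine-readable result (exact supports, T as a decimal
string, coverage per sequence).

Other subcommands: `alnsafe render` (graph image, optionally with a
custom D/V/H move-string path), `alnsafe structmap` (per-residue window
annotations on a structure chain), `alnsafe experiment` (seeded synthetic
divergence experiment). `alnsafe <cmd> --help` lists the flags.

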