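# Methods

This note documents the models implemented in `motiffold`, the defaults
and the reasoning behind them, the numerical choices, and what the
synthetic benchmark does and does not establish.

## The probabilistic-sequence representation

An alignment is folded as one object: per kept column a nucleotide
frequency 4-vector (gaps excluded, ambiguity codes spread uniformly over
their residue sets, optional per-sequence weights, uniform by default),
and per column pair a joint 4×4 frequency computed over the sequences
that carry a residue at both columns. Sequences gapped at exactly one of
the two columns are excluded from the pair count — the joint then
normalizes cleanly and its marginals match the single-column vectors on
gapless data. Columns with more than `gap_max` gaps (default 0.75) are
removed before folding; highly gappy regions are alignment-insertion
artifacts that would otherwise dilute both covariation and motif signal.
A `ColumnMap` translates kept indices back to 1-based original columns in
every output. A single sequence is the S=1 special case: all columns are
point masses and every emission reduces to plain sequence scoring.

## Grammars

`RBGJ3J4` renders the RNA basic grammar with three- and four-way
junctions split out from higher multiloops (they are by far the most
common multiloops in known structures, and they are where many motifs
live). Concretely:

    S → aS | F0 S | ε;   F0 → aF5a′ | aPa′;   F5 → aF5a′ | aPa′ (stacked)
    P → m…m | m…m F0 | F0 m…m | m…m F0 m…m | J3 | J4 | JN
    J3 → BB BB BT;  J4 → BB BB BB BT;  JN → BB BB BB M1 R
    M1 → BB M1 | BB;  BB → m…m F0;  BT, R → m…m

Unpaired runs `m…m` have geometric length distributions over the excess
above a per-context minimum (hairpin 3, bulge/internal-loop strand 1,
multiloop branch 0) with a single shared excess parameter; residues in
runs use the single-nucleotide emission table. Helix-opening pairs use
the 4×4 pair table; pairs directly inside another pair (the F5 context)
use a 16×16 conditional stacking table mixed over the enclosing pair's
column frequencies. The grammar is unambiguous: a given pair set (plus
motif annotation, below) has exactly one derivation, which the test suite
verifies by exhaustive enumeration.

A deliberate steric constraint: every pair must enclose at least three
columns, in every grammar, motif rules included (covariation-forced pairs
are exempt). Hairpin loops of one or two nucleotides are physically
impossible, and without this floor the motif rules — whose profile HMMs
can delete their way down to a single residue — produced absurd one-
nucleotide "motif hairpins" whenever a constraint forced a tight helix.
No modeled hairpin motif has a consensus loop under three residues, so
nothing real is excluded.

Pseudoknot layers use the classic unambiguous G6-style stacking grammar
(`S → LS | L; L → aFa′ | a; F → aFa′ | LS`) with the same emission
tables. Its three transition distributions are fixed sensible defaults
rather than trained values: layers ≥ 2 are folded under hard constraints
and only helices containing a forced covarying pair are retained, so
these probabilities have essentially no influence on output.

## Motif library and variants

A motif descriptor names one of six architectures — hairpin loop (HL),
bulge (BL), internal loop (IL), three-way (J3) and four-way (J4)
junction, branch segment (BS) — and gives IUPAC consensus strings for its
sequence segments. The text format is one record per line
(`CLASS NAME key=value…`, `#` comments, empty value = empty-but-modeled
segment). Motifs bounded by more than one helix exist in topological
variants depending on which end attaches to the rest of the structure:
two for BL (left/right bulge) and IL (outer vs inner helix as the
attachment, which swaps the strands), three rotations for J3, four for
J4. Variants whose class and rotated segment tuple coincide are merged
(the bundled all-empty coaxial J4 collapses from four rotations to one);
left and right bulges are never merged because they generate different
structures. The nonredundant count is reported in the run log.

The bundled library holds the motifs whose consensus is given explicitly
in the primary literature (GNRA, U-turn, the K-turn's RNN strand and G·A
stem pairs, loop E's five-per-branch, the group II intron J3) plus
curator-completed consensus strings for UNCG, C-loop, a hammerhead-style
J3, a coaxial J4 and the CsrA-binding branch segment; the file header
marks them as curated. Any library can be substituted via `--r3dfile`.

## Profile HMMs

Each segment gets a profile HMM with one match state per consensus
position, insert states at every slot (including flanks) and deletion
bypasses; emissions are on transitions, and an empty consensus is still a
valid model (inserts only), so empty segments can absorb insertions.
Match emissions: a consensus class of size `c` gives each in-class
residue `(1−(4−c)·ε)/c` and each out-of-class residue `ε` (default
`10⁻⁴`); this reproduces p(U)=0.9997 and p(A)=p(G)=0.4999 and
generalizes to all IUPAC classes (an N position is exactly uniform).
Insert emissions default to uniform, overridable from the parameter file
(training-set residue frequencies are not available here).

Transitions use a two-parameter family: one geometric self-insert
probability `q` shared by all slots and one per-position delete
probability `d` (default 0.05 — motif instances shortened by a residue
are seen in real structures but are uncommon). The expected emitted
length is `L(1−d) + (L+1)·q/(1−q)`, and `q` is solved in closed form so
this equals `L + min(0.1·L, 1.5)`; an empty consensus keeps an expected
excess of 0.5 so insertions remain reachable. Segment scoring uses the
forward algorithm over column-frequency mixtures
(`P(o) = Σ_a p_o(a)·P(a)`), in log space throughout. The model is a
proper distribution over strings, so forward scores drop into the
grammar as normalized emissions without extra length corrections.

## Motif rules inside the grammar

Hairpin and bulge motifs score a loop span as the best (CYK) or summed
(inside) ordered segmentation of the span into their segment chain;
internal-loop motifs segment both strands around the enclosed helix;
junction motifs interleave their branch segments with the enclosed
helices; branch segments replace one multiloop branch's unpaired run.
The motif annotation records the segment boundaries, which keeps the
extended grammar unambiguous (two segmentations of the same span are two
different annotations). Rule mass: a class fraction `f` (defaults 0.4,
0.4, 0.5, 0.2, 0.2, 0.2 for HL, BL, IL, J3, J4, BS) is split off the
generic rule and shared equally among the variants attaching at that
rule; the total mass leaving every loop rule is conserved, and an empty
library returns it all to the generic rule, making the extended grammar
collapse exactly onto the base grammar.

For tractability each motif segment is capped at its consensus length
plus 8 columns (the expected excess is at most 1.5, so the truncated tail
carries negligible probability); generic bulge and internal-loop strands
are capped at 30 columns, standard practice in folding programs. The
enumeration oracle applies identical caps, so the oracle-equivalence
tests are exact, not approximate.

## Training by counting

Because the grammar is unambiguous, an annotated secondary structure
determines a unique derivation; transition probabilities are rule-usage
frequencies with +1 pseudocounts, emission tables are observed
residue/pair/stack frequencies with +1 pseudocounts, and the run-length
parameter is the (lightly smoothed) geometric MLE of run excesses. The
shipped default parameters are trained on a small bundled set of curated
toy structures (labelled synthetic; it covers every rule family:
stacks, hairpins, both bulges, internal loops, J3/J4/5-way junctions,
external runs), with the multiloop mass re-split 51% / 32% / 17% for
J3 / J4 / higher junctions — the junction frequencies reported for large
curated structure collections. Parameter files (JSON, schema-versioned,
bit-exact round trip) can replace everything. A parameter-recovery test
samples parses from known parameters and verifies counting re-estimates
the transitions within ±0.02 at 10⁴ parses.

## Folding engine

CYK and inside share one dynamic program over half-open kept-column
spans, one numpy table per nonterminal, filled by increasing width with
vectorized split maxima/log-sums; multiway junction rules are binarized
internally (helper nonterminals are deterministic bookkeeping and do not
affect the derivation semantics). Backpointers are recorded in max mode;
the traceback re-derives motif segmentations from the chain tables.
Tie-breaking among equal-probability derivations is by first-found
candidate in a fixed enumeration order (generic rules before motif rules,
splits left to right), which makes outputs reproducible; exact float ties
between distinct derivations essentially only arise in degenerate
uniform-parameter cases.

Constraints are hard masks. A forced pair's columns cannot be emitted
unpaired, cannot sit inside a motif segment or unpaired run, and cannot
pair with any other partner, so every finite-score derivation contains
the pair; forbidden pairs and unpairable positions score −∞ as pair
emissions. An unsatisfiable constraint set surfaces as an explicit
infeasibility error, with the offending layer named in multilayer runs.
Scores use log space throughout; zero-probability emissions become −∞
directly (no underflow flooring is needed at double precision for the
problem sizes involved).

The engine's correctness is anchored to a brute-force enumeration oracle
that lists every derivation with its probability, pair set and
annotation; CYK must match the enumerated maximum and inside the
enumerated sum to 1e-9 on every two-letter input up to length 8, under
both grammars, and the enumeration must contain no duplicate
(structure, annotation) — the unambiguity property. A rescoring walk
(structure + motif calls → unique derivation → score) verifies that every
traceback reproduces its table optimum.

## Covariation layers

The primary evidence path is a TSV of positive/negative pairs with
E-values from an external covariation analyzer (default threshold 0.05).
The built-in stand-in — average-product-corrected mutual information with
empirical E-values from the maximum statistic over column-shuffled
alignments — is clearly labelled an approximation: it has no phylogenetic
correction, produces no negative pairs, and its E-values are family-wise
empirical p-values. On shuffled (null) alignments its positive rate is
calibrated below the threshold; on planted covarying helices at
compensatory rate 0.5 and 50 sequences it ranks every planted pair above
every background pair.

Positive pairs are decomposed into layers by repeatedly extracting the
maximum-cardinality mutually nested subset (interval DP; ties broken by
the lexicographically smallest pair list, verified optimal against
exhaustive subset search). Layer 1 is folded with the motif grammar;
each later layer folds the whole sequence with the stacking grammar,
forbidding all previously placed pairs, and keeps only helices that
contain at least one of its covarying pairs — this is how pseudoknots
and other tertiary pairs enter. Positions paired in more than one layer
are reported as conflicts and left for the user.

Support: a motif is covariation-supported when at least one bounding
helix contains a positive pair. Bounding helices are the helix whose
innermost pair closes the motif's loop plus, for multibranch motifs,
every helix enclosed in the motif span; for branch segments, the helices
whose stack abuts either end of the segment (the junction's own closing
helix is deliberately not counted for BS motifs — a choice the evidence
definition leaves open). The FDR report divides control-run supported
(and unsupported) counts by the corresponding real-run counts; zero
denominators report as undefined rather than raising.

## Synthetic benchmark

The generator plants covarying helices (each pair drawn from the six
canonical pairs with GC-rich stationary weights; per sequence, with the
compensatory rate the pair is redrawn jointly, which preserves
Watson–Crick pairing while decorrelating sequences), motif columns
(sampled within the consensus class, mutated uniformly at the motif's
rate) and iid background. Sequences are exchangeable — no phylogeny, no
indels — which is exactly the regime where the column-shuffling null of
the stand-in statistic is correct. Truth records the planted pairs and
exact motif ends; a prediction counts only on exact name + both-ends
match, and every other call is a false positive.

The benchmark replicate is one 70-column, 50-sequence alignment carrying
a GNRA tetraloop hairpin and a K-turn internal loop, compensatory rate
0.5, motif mutation rate 0.05. Per replicate, covarying pairs are
extracted with the stand-in statistic and three individual sequences are
folded with a two-motif library, once forcing the layer-1 nested
covarying pairs and once unconstrained. Across 20 seeded replicates,
constrained folding is substantially more sensitive and less
false-positive-prone (typical run: ≈94% vs ≈55% sensitivity, ≈0.25 vs
≈0.78 FP/sequence; sign test p ≪ 0.05). This demonstrates the
covariation-constraint mechanism under controlled conditions; it does not
certify accuracy on real alignments, where phylogenetic correlation,
indels, alignment error and motif divergence all degrade both the
covariation statistic and the motif models.

## Problem sizes and determinism

Exhaustive oracle sweeps use two-letter inputs up to length 8 (both
grammars, max and sum, ≈2.5 min); profile-HMM path-sum checks cover all
segments to length 4 against models to consensus length 3; layer
decomposition is verified against exhaustive search on 500 random sets of
up to 12 pairs; parameter recovery uses 10⁴ sampled parses; the benchmark
uses 20 replicates. Every stochastic component takes an explicit seed
(generator, shuffles, samplers), and identical configuration plus seed
reproduces byte-identical CLI output.

## Known limitations

- The stand-in covariation statistic is not phylogenetically corrected
  and supplies no negative pairs; serious use should feed an external
  analyzer's pair list.
- Default grammar parameters come from a small curated structure set;
  they are sensible but not competitive with parameters trained on large
  annotated corpora, and should be replaced via `train_by_counting` for
  production use.
- Stacking emissions condition on the enclosing pair through independent
  column mixtures, an approximation for strongly covarying alignments.
- Motif segment caps truncate pathologically long insertions; generic
  loop strands are capped at 30 columns.
- Lone base pairs are heavily penalized by the default parameters (the
  training set contains none), although the grammar expresses them.
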