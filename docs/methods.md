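# Methods

This note documents the models, conventions and design choices behind
`rnamotifbench`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## Secondary-structure model

A secondary structure over a sequence of length *n* is a set of base pairs
(i, j), 1 ≤ i < j ≤ n, in which each position is paired at most once. Two
pairs (i, j) and (k, l) *cross* when their arcs interleave
(i < k < j < l); a structure containing a crossing couple is flagged
pseudoknotted. Pairs sharing a position are reported as paired-once
violations, not as crossings. All public coordinates are 1-based inclusive,
the convention of connectivity tables; helpers convert to 0-based half-open
for internal array work.

Dot-bracket parsing matches each bracket class — `()`, `[]`, `{}`, `<>` —
independently with a stack. On writing, crossing pairs are greedily
2-coloured (round brackets first, square second); patterns needing a third
class raise a capability error rather than silently dropping pairs. WUSS
consensus annotations additionally accept matched upper/lowercase letters
for pseudoknot classes, and `. , _ : ~ -` as unpaired/gap columns.

Sequences are uppercased and `T` is normalised to `U` so DNA-alphabet FASTA
files are tolerated; IUPAC ambiguity letters are accepted and flagged.

### Connectivity tables

The CT writer/reader uses the common six-column dialect (index, base,
previous index, next index, pairing partner, natural numbering). A second
dialect (`nextprev`) that lists the next index before the previous one is
available as a switch; both read back to identical structures, so the
choice only matters for interoperability with other CT producers.

### Consensus projection

A consensus pair is projected onto an alignment row through the row's
column map; any pair with a gap in either column for that row is dropped.
Since deleting arcs cannot create crossings, projecting a nested consensus
always yields a nested per-sequence structure. Non-canonical projected
pairs (e.g. A–G after substitution) are kept by default — the curated
alignment is the truth — with an optional canonical-only filter.

## Loop decomposition and complexity tiers

Every base pair closes exactly one face of the planar diagram, typed
hairpin (no enclosed pair), stack (one enclosed pair, no unpaired bases),
bulge (unpaired on one side), internal loop (unpaired on both sides), or
multiloop (≥ 2 enclosed pairs, i.e. ≥ 3 pairs bounding the face). Runs of
consecutive unpaired bases outside all pairs form external elements. Two
identities follow and are enforced by tests: non-external faces equal the
pair count, and hairpin faces equal innermost pairs.

For stratification, stack faces are collapsed into helices (maximal stacked
runs; an isolated pair is a degenerate helix of size 1), so an
uninterrupted stem-loop counts as **one** loop however long its helix. The
*loop count* tallies hairpins, bulges, internal loops, multiloops and
external elements; the *type count* is the number of distinct kinds among
{hairpin, bulge, internal, multiloop} present. Default tier bands:

| tier       | loop count | type count | character                  |
|------------|-----------:|-----------:|----------------------------|
| Ref.1-like | 1–2        | 1–2        | simple stem-loops          |
| Ref.2-like | 5–7        | 2–3        | branched, moderate         |
| Ref.3-like | 8–17       | 4–5        | large multi-branched folds |

The bands are user-configurable (overlapping definitions are rejected), and
the classifier also accepts raw (loops, types) tuples for counts taken from
external annotation. Whether published family complexity counts refer to
faces or helices is not standardised; the collapsed-helix counter is this
package's definition and is stated here rather than attributed elsewhere.

## Energy models

Three model families, lowest fidelity first:

* **Per-pair**: `Ep(S) = Σ e(i, j)` with `e` keyed by the unordered base
  combination; internal (same-strand) and external bonds may carry separate
  tables but default to one. Linear in the table by construction.
* **Stacked-pair**: pair (i, j) contributes a constant `Es` iff
  (i+1, j−1) ∈ S; an isolated pair scores 0 and a helix of stacking size L
  scores (L−1)·Es.
* **Loop (nearest-neighbour)**: the structure is decomposed and each loop
  contributes by type — hairpins by loop size plus an optional terminal
  mismatch addend, stacks by the ordered pair types, bulges by length plus
  a closing-pair addend, internal loops by total unpaired length plus an
  adjacent-base addend, multiloops by the affine form
  `a + b·branches + c·unpaired`. External elements contribute nothing.
  The affine multiloop form is the standard operationalisation of
  "a function of the number of helices and free ends".

Parameter tables are JSON/YAML files; size lookups extrapolate linearly
beyond the largest listed size. The shipped table (hairpin +5.4 at size 3,
+0.5 per extra base; stack −2.0; bulge +3.0; internal +2.0; multiloop
a = 3.4, b = 0.4, c = 0) is a small demonstration set in arbitrary units,
deliberately *not* a fitted thermodynamic parameter set: the model
structure, not particular numbers, is what the package provides. Energy
minimisation/structure prediction is out of scope.

## Benchmark generation

Pipeline per family: project the motif for every alignment row → remove
rows whose motif occurs reverse-complemented → sample at most
`max_per_family` rows without replacement → attach `flank_total` nt of
flanking sequence, the 5′ share uniform on 0..total → discard records with
ambiguity letters. Defaults (`flank_total=200`, `max_per_family=50`) are
the study conditions this framework models; scalability studies vary
`flank_total`, which provably changes only sequence lengths, never the
truth structures.

Two deliberately open points are resolved as follows:

* **Flank source.** Retrieval of real genomic context from an archive is a
  network operation and out of scope; flanks come either from user-provided
  context sequences (sliced around the motif occurrence) or from a seeded
  synthetic generator with configurable base composition (uniform by
  default). Synthetic flanks have no compositional bias, repeats or
  homology — benchmarks built with them test coordinate and structure
  recovery, not robustness to genomic background.
* **Reverse-complement rule.** "Motif appearing in the reverse complement"
  is ambiguous between minus-strand annotation and literal recurrence. The
  implemented default removes a row when the reverse complement of its
  motif occurs in its own context (or in the motif itself when no context
  is given); the filter can be disabled.

Every run is bit-reproducible from the seed recorded in the manifest. The
manifest (TSV + JSON) carries per-record truth: motif coordinates,
dot-bracket structure, complexity tier, source row and seed.

## Scoring

The shift-tolerant TP rule and the metric definitions are given in the
README. Conventions worth stating:

* **TN universe**: all C(n, 2) position pairs of the full benchmark
  sequence. Specificity has no canonical universe at base-pair level; the
  choice is emitted as a `universe` tag in every report so alternative
  universes remain distinguishable downstream.
* **Matching mode**: the per-pair rule is the default (the literal reading
  of "a discovered pair is TP if ..."); one-to-one maximum matching
  (Hopcroft–Karp) is the stricter option. Per-pair TP ≥ one-to-one TP
  always; they agree whenever compatibility is a partial matching.
* **0/0 conventions**: with an empty reference, Sn is 1 only if the
  prediction is also empty, otherwise undefined; PPV is undefined with no
  predictions. Undefined values are excluded from averages and their
  counts reported.
* **Selection**: tools may report up to ten ranked motifs per record; the
  best-scoring one (ties to the lowest rank; score direction configurable)
  is evaluated. A record with no predictions scores all reference pairs as
  FN.
* **Aggregation**: two-level macro averaging — records within family, then
  families — so families with many records do not dominate. Pooled
  averaging is deliberately not the default; it is recoverable from the
  per-record table every report includes.
* **Coordinate recovery**: predictions lacking absolute coordinates are
  located by exact substring search; multiple occurrences raise an
  ambiguity error listing the positions unless the first-hit policy is
  requested.
* **ANOVA**: one-way fixed-effects decomposition computed from sums of
  squares; p-value and critical value from the F distribution at
  α = 0.05 by default. All groups constant with equal means → F reported
  as NaN (0/0); equal means with within-group variance → F = 0.

## Synthetic fixtures

The generators emulate seed-alignment families: a random nested structure
(minimum hairpin loop of 3 unpaired bases, a standard steric constraint), a
structure-compatible master sequence (paired positions drawn from
Watson–Crick plus wobble combinations, unpaired uniform), rows mutated
pair-preservingly and gapped per column. What they do **not** emulate:
covariation statistics of real families, phylogenetic correlation between
rows, indel structure (gaps are independent per column), or genomic flank
composition. Passing tests therefore demonstrate correctness of the
machinery — coordinate bookkeeping, filtering, matching, metric arithmetic
— not discovery performance on real RNA.

Perturbation fixtures make the scorer's contract exact rather than
statistical: kept pairs are copied; shifted pairs move one nucleotide on
one side and are constrained to shift-match *only their own* source pair;
spurious pairs are sampled outside the ±1 neighbourhood of every reference
pair. The implied confusion counts (TP = kept + shifted, FP = added,
FN = deleted) then hold by construction, and the suite checks the scorer
reproduces them exactly on hundreds of seeded fixtures.

Tier-targeted structure generation assembles stems, bulges, internal loops
and multiloops to hit a tier's loop/type bands, then spends the remaining
length budget on profile-neutral knobs (hairpin size, helix length,
multiloop spacers) so the requested sequence length is met exactly; a
closed-loop check against the classifier guards the result.

## Problem sizes

The shipped verification runs use: 1,000 random structures (lengths 5–80)
for round trips and loop identities, 500 perturbation fixtures, 200 random
instances (≤ 8 pairs per side) against the exhaustive matching oracle,
80-row families with 50-record benchmarks for the pipeline checks. These
sizes give exact (not sampled) agreement on every check while keeping the
default suite fast to run routinely.

## Known limitations

* Writing pseudoknots is limited to two bracket classes; structures whose
  crossing graph is not 2-colourable are representable in memory and in CT
  but not in dot-bracket output.
* Loop decomposition and the loop energy model require nested input;
  pseudoknotted truth structures are carried through benchmarks but
  tier-classified as "unclassified".
* Inter-molecular pairs, base triples and covariance-model representations
  are out of scope.
* The scoring engine evaluates base pairs only; nucleotide-level overlap
  and alignment-quality measures are not computed.
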