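# rnamotifbench

Benchmark generation and base-pair-level scoring for **structural RNA motif
discovery**.

Structural motifs are recurring patterns of conserved base pairs: a set of
RNAs can share a common fold even when their primary sequences have
diverged. Tools that discover such motifs in unaligned sequences are hard to
compare because there is no gold-standard benchmark and every tool reports
its results in a different shape. This package provides the missing
assessment loop for tool developers and evaluators:

* a canonical secondary-structure data model with converters between
  dot-bracket notation, connectivity tables (CT), FASTA and Stockholm seed
  alignments, including projection of a gapped consensus structure onto
  individual sequences;
* loop decomposition (hairpin / stack / bulge / internal / multiloop /
  external) and a complexity profile that stratifies structures into tiers
  from simple stem-loops to complex multi-branched folds;
* three free-energy model families (per-pair, stacked-pair, loop
  nearest-neighbour) with pluggable parameter tables;
* a **benchmark generator** that implants reference motifs (e.g. a seed
  alignment's per-sequence structure) into flanking sequence — by default
  200 nt randomly split between the 5′ and 3′ ends, at most 50 sequences
  per family, with reverse-complement and ambiguity filtering — and writes
  a machine-readable truth manifest;
* a **scoring engine** that evaluates tool predictions at base-pair level.

## The statistic at the core

For a benchmark record with reference pair set *S* and predicted pair set
*P*, a predicted pair (i, j) is a true positive under the *shift-tolerant
rule* if the reference contains (i, j), (i±1, j) or (i, j±1) — identical or
shifted by one nucleotide on exactly one side. From the confusion counts,

```
Sn = TP / (TP + FN)      PPV = TP / (TP + FP)      Sp = TN / (TN + FP)
```

with the true-negative universe taken as all C(n, 2) position pairs of the
record. The default *per-pair* mode applies the rule to each predicted pair
independently; a stricter *one-to-one* mode computes the maximum matching
in the bipartite compatibility graph. Per-record metrics are macro-averaged
within families and then across families; a one-way ANOVA over per-record
values supports tool-versus-tool comparisons.

## Worked example

```python
from rnamotifbench import parse_dbn, score_pairs
from rnamotifbench.scoring import metrics_from_counts

truth = parse_dbn("(((...)))..((....))")   # two stems, n = 19
pred  = parse_dbn(".((...))...((...)).")   # outer pair lost, 2nd stem shifted
c = score_pairs(pred.pairs, truth.pairs, n=19)
m = metrics_from_counts("demo", "fam", c)
print(f"TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
print(f"Sn={m.sn:.3f} PPV={m.ppv:.3f} Sp={m.sp:.4f}")
```

prints

```
TP=4 FP=0 FN=1 TN=166
Sn=0.800 PPV=1.000 Sp=1.0000
```

The predicted pairs (2,8) and (3,7) are exact matches; (12,18) and (13,17)
are one-side shifts of the reference pairs (12,19) and (13,18) and still
count as true positives; the lost outer pair (1,9) is the single false
negative, giving Sn = 4/5.

The same loop runs from the shell. Build a synthetic family, generate a
benchmark with the default settings, then score predictions given in the
tab-separated interchange format (record id, rank, score, start, end,
dot-bracket or motif text per line):

```bash
rnamotifbench fixtures --rows 30 --length 70 --tier Ref.2-like --seed 5 --out fam.sto
rnamotifbench generate --alignment fam.sto --seed 5 --out bench/
rnamotifbench score --manifest bench/manifest.json --fasta bench/benchmark.fasta \
    --predictions preds.tsv --out report
rnamotifbench compare report_toolA.json report_toolB.json
```

Predictions lacking absolute coordinates (tools that report only the motif
text) are located by substring search against the benchmark sequence; up to
ten ranked motifs per record are accepted and the best-scoring one is
evaluated.

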