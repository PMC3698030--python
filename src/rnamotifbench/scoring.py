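"""Base-pair-level evaluation of predicted motifs against benchmark truth.

A predicted base pair counts as a true positive under the shift-tolerant
rule: it must be identical to a reference pair or shifted by one nucleotide
on exactly one side, i.e. for a reference pair ``(i, j)`` any of ``(i, j)``,
``(i+1, j)``, ``(i-1, j)``, ``(i, j+1)``, ``(i, j-1)`` counts.  From the
confusion counts the engine reports sensitivity ``Sn = TP/(TP+FN)``,
positive predictive value ``PPV = TP/(TP+FP)`` and specificity
``Sp = TN/(TN+FP)``, where the true-negative universe is, by default, all
position pairs ``1 <= i < j <= n`` of the benchmark sequence.

Two matching modes ship: the default *per-pair* mode applies the rule to
each predicted pair independently; the stricter *one-to-one* mode takes a
maximum-cardinality matching in the bipartite compatibility graph so one
reference pair cannot absolve two predictions.

Aggregation is two-level macro averaging: per-record metrics are averaged
within each family, family means are averaged for the overall figure.  A
one-way ANOVA over per-record metric values supports comparing tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .benchmark import BenchmarkRecord
from .core import BasePair

__all__ = [
    "MotifPrediction",
    "ConfusionCounts",
    "RecordMetrics",
    "MetricsReport",
    "AnovaResult",
    "CoordinateResolutionError",
    "is_shift_match",
    "score_pairs",
    "metrics_from_counts",
    "resolve_coordinates",
    "select_best",
    "score_record",
    "aggregate",
    "anova_oneway",
    "read_predictions",
    "write_predictions",
]


def is_shift_match(p: BasePair, r: BasePair) -> bool:
    """Shift-tolerant equality: identical, or off by one on exactly one side."""
    di, dj = p.i - r.i, p.j - r.j
    return (di == 0 and abs(dj) <= 1) or (dj == 0 and abs(di) <= 1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def score_pairs(
    predicted: Iterable[BasePair],
    reference: Iterable[BasePair],
    n: int,
    mode: str = "per-pair",
) -> ConfusionCounts:
    """Confusion counts for a predicted pair set against the reference.

    ``mode="per-pair"`` (default): a predicted pair is TP when it
    shift-matches any reference pair; a reference pair is missed (FN) when
    no predicted pair shift-matches it.  ``mode="one-to-one"``: TP is the
    size of a maximum matching in the bipartite graph of shift-compatible
    (predicted, reference) couples, so the counts satisfy
    ``TP + FP = |predicted|`` and ``TP + FN = |reference|`` exactly.

    TN is counted over the universe of all ``C(n, 2)`` position pairs.
    """
    pred = sorted({p if isinstance(p, BasePair) else BasePair(*p)
                   for p in predicted})
    ref = sorted({r if isinstance(r, BasePair) else BasePair(*r)
                  for r in reference})
    for p in pred + ref:
        if p.j > n:
            raise ValueError(f"pair {p.as_tuple()} outside sequence of length {n}")
    if mode == "per-pair":
        tp = sum(1 for p in pred if any(is_shift_match(p, r) for r in ref))
        fp = len(pred) - tp
        fn = sum(1 for r in ref if not any(is_shift_match(p, r) for p in pred))
    elif mode == "one-to-one":
        tp = _max_matching_size(pred, ref)
        fp = len(pred) - tp
        fn = len(ref) - tp
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    universe = n * (n - 1) // 2
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=max(tn, 0))


def _max_matching_size(pred: list[BasePair], ref: list[BasePair]) -> int:
    graph = nx.Graph()
    left = [("p", k) for k in range(len(pred))]
    right = [("r", k) for k in range(len(ref))]
    graph.add_nodes_from(left, bipartite=0)
    graph.add_nodes_from(right, bipartite=1)
    for a, p in enumerate(pred):
        for b, r in enumerate(ref):
            if is_shift_match(p, r):
                graph.add_edge(("p", a), ("r", b))
    matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=left)
    return sum(1 for node in matching if node[0] == "p")


@dataclass(frozen=True)
class RecordMetrics:
    """Per-record metrics; ``None`` marks an undefined (0/0) ratio, which is
    excluded from averages and counted in the report."""

    record_id: str
    family: str
    counts: ConfusionCounts
    sn: float | None
    ppv: float | None
    sp: float | None


def metrics_from_counts(
    record_id: str, family: str, c: ConfusionCounts
) -> RecordMetrics:
    """Sn/PPV/Sp from confusion counts with explicit 0/0 conventions.

    An empty reference with an empty prediction scores Sn = 1 (nothing to
    find, nothing claimed); an empty reference with predictions leaves Sn
    undefined.  PPV is undefined when there are no predictions.
    """
    if c.tp + c.fn > 0:
        sn = c.tp / (c.tp + c.fn)
    else:
        sn = 1.0 if c.fp == 0 else None
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
    return RecordMetrics(record_id, family, c, sn, ppv, sp)


# ---------------------------------------------------------------------------
# predictions

@dataclass(frozen=True)
class MotifPrediction:
    """One motif reported by a discovery tool for one benchmark record.

    Coordinates are absolute (full-sequence, 1-based) when present; tools
    that report only the motif text leave ``start``/``end`` unset and the
    pairs in motif-local coordinates until :func:`resolve_coordinates`.
    """

    record_id: str
    rank: int
    score: float
    start: int | None = None
    end: int | None = None
    pairs: frozenset[BasePair] = field(default_factory=frozenset)
    motif_text: str = ""

    @property
    def resolved(self) -> bool:
        return self.start is not None and self.end is not None


class CoordinateResolutionError(ValueError):
    """Motif text not located (or not located uniquely) in the record."""

    def __init__(self, message: str, positions: tuple[int, ...] = ()):
        super().__init__(message)
        self.positions = positions


def resolve_coordinates(
    pred: MotifPrediction,
    record: BenchmarkRecord,
    take_first: bool = False,
) -> MotifPrediction:
    """Fill in absolute coordinates via exact substring search.

    Predictions that already carry coordinates pass through unchanged.
    Otherwise the motif text is located in the record's full sequence; the
    motif-local pairs are shifted to absolute coordinates.  Zero matches
    raise; multiple matches raise unless ``take_first``.
    """
    if pred.resolved:
        return pred
    if not pred.motif_text:
        raise CoordinateResolutionError(
            f"prediction for {pred.record_id!r} has neither coordinates "
            "nor motif text"
        )
    haystack = record.sequence.residues
    needle = pred.motif_text.upper().replace("T", "U")
    hits = []
    at = haystack.find(needle)
    while at >= 0:
        hits.append(at + 1)
        at = haystack.find(needle, at + 1)
    if not hits:
        raise CoordinateResolutionError(
            f"motif text not found in record {record.identifier!r}"
        )
    if len(hits) > 1 and not take_first:
        raise CoordinateResolutionError(
            f"motif text occurs {len(hits)} times in record "
            f"{record.identifier!r} at positions {hits}",
            positions=tuple(hits),
        )
    start = hits[0]
    offset = start - 1
    return replace(
        pred,
        start=start,
        end=start + len(needle) - 1,
        pairs=frozenset(p.shifted(offset, offset) for p in pred.pairs),
    )


def select_best(
    preds: Sequence[MotifPrediction],
    limit: int = 10,
    higher_is_better: bool = True,
) -> MotifPrediction | None:
    """Best-scoring motif among a record's ranked predictions.

    At most ``limit`` predictions (lowest ranks) are considered; ties on
    score go to the lowest rank.  Returns ``None`` for an empty list — the
    caller scores that as all-FN.
    """
    pool = sorted(preds, key=lambda p: p.rank)[:limit]
    if not pool:
        return None
    sign = 1 if higher_is_better else -1
    return max(pool, key=lambda p: (sign * p.score, -p.rank))


def score_record(
    record: BenchmarkRecord,
    preds: Sequence[MotifPrediction],
    mode: str = "per-pair",
    limit: int = 10,
    higher_is_better: bool = True,
    take_first: bool = False,
) -> RecordMetrics:
    """Resolve, select and score one record's predictions against its truth."""
    best = select_best(preds, limit=limit, higher_is_better=higher_is_better)
    reference = record.absolute_truth_pairs()
    n = len(record.sequence)
    if best is None:
        counts = score_pairs(frozenset(), reference, n, mode=mode)
    else:
        best = resolve_coordinates(best, record, take_first=take_first)
        counts = score_pairs(best.pairs, reference, n, mode=mode)
    return metrics_from_counts(record.identifier, record.family, counts)


# ---------------------------------------------------------------------------
# aggregation

@dataclass(frozen=True)
class MetricsReport:
    """Per-record metrics with family and overall macro means."""

    per_record: tuple[RecordMetrics, ...]
    family_means: dict[str, dict[str, float | None]]
    overall: dict[str, float | None]
    undefined_counts: dict[str, int]
    mode: str = "per-pair"
    universe: str = "all-pairs-full-sequence"

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "universe": self.universe,
            "overall": self.overall,
            "family_means": self.family_means,
            "undefined_counts": self.undefined_counts,
            "per_record": [
                {
                    "id": m.record_id,
                    "family": m.family,
                    "tp": m.counts.tp,
                    "fp": m.counts.fp,
                    "fn": m.counts.fn,
                    "tn": m.counts.tn,
                    "sn": m.sn,
                    "ppv": m.ppv,
                    "sp": m.sp,
                }
                for m in self.per_record
            ],
        }


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return sum(defined) / len(defined) if defined else None


def aggregate(
    per_record: Sequence[RecordMetrics],
    mode: str = "per-pair",
    universe: str = "all-pairs-full-sequence",
) -> MetricsReport:
    """Two-level macro averaging: records within family, then families.

    Undefined (0/0) per-record values are excluded from means and tallied
    in ``undefined_counts``.
    """
    if not per_record:
        raise ValueError("nothing to aggregate")
    families: dict[str, list[RecordMetrics]] = {}
    for m in per_record:
        families.setdefault(m.family, []).append(m)
    family_means: dict[str, dict[str, float | None]] = {}
    for fam, members in sorted(families.items()):
        family_means[fam] = {
            metric: _mean_defined([getattr(m, metric) for m in members])
            for metric in ("sn", "ppv", "sp")
        }
    overall = {
        metric: _mean_defined([fm[metric] for fm in family_means.values()])
        for metric in ("sn", "ppv", "sp")
    }
    undefined = {
        metric: sum(1 for m in per_record if getattr(m, metric) is None)
        for metric in ("sn", "ppv", "sp")
    }
    return MetricsReport(
        per_record=tuple(per_record),
        family_means=family_means,
        overall=overall,
        undefined_counts=undefined,
        mode=mode,
        universe=universe,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA for tool comparison

@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    f_critical: float
    df_between: int
    df_within: int
    alpha: float

    @property
    def significant(self) -> bool:
        return not math.isnan(self.f_statistic) and (
            self.f_statistic > self.f_critical
        )


def anova_oneway(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way fixed-effects ANOVA over per-tool metric values.

    The F statistic is computed from the between/within sum-of-squares
    decomposition; p-value and the critical value at ``alpha`` come from
    the F distribution with the decomposition's degrees of freedom.  When
    every group is constant and all means coincide the statistic is 0/0 and
    reported as NaN.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups
    )
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_crit = float(stats.f.ppf(1 - alpha, df_between, df_within))
    if ms_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(
                float("nan"), float("nan"), f_crit, df_between, df_within, alpha
            )
        return AnovaResult(
            float("inf"), 0.0, f_crit, df_between, df_within, alpha
        )
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(f_stat, p, f_crit, df_between, df_within, alpha)


# ---------------------------------------------------------------------------
# prediction interchange format

_FIELD_SEP = "\t"
_ABSENT = "."


def read_predictions(path) -> dict[str, list[MotifPrediction]]:
    """Read the tab-separated interchange format, grouped by record.

    Per line: record id, rank, score, start, end, dot-bracket structure or
    motif text; ``.`` marks an absent field.  Two dialects are covered by
    the same reader: coordinate-bearing lines carry start/end plus a
    dot-bracket string, sequence-only lines carry ``.`` coordinates plus
    the motif text (resolved later against the benchmark).
    """
    from pathlib import Path

    from .core import parse_dbn

    out: dict[str, list[MotifPrediction]] = {}
    for line_no, raw in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split(_FIELD_SEP)
        if len(cols) != 6:
            raise ValueError(
                f"{path}:{line_no}: expected 6 tab-separated fields, "
                f"got {len(cols)}"
            )
        rec_id, rank_s, score_s, start_s, end_s, payload = cols
        rank = int(rank_s)
        score = float(score_s) if score_s != _ABSENT else 0.0
        start = int(start_s) if start_s != _ABSENT else None
        end = int(end_s) if end_s != _ABSENT else None
        payload = payload.strip()
        if payload and set(payload) <= set("().[]{}<>"):
            local = parse_dbn(payload)
            offset = (start - 1) if start else 0
            pairs = frozenset(
                p.shifted(offset, offset) for p in local.pairs
            )
            motif_text = ""
            if start is not None and end is None:
                end = start + local.n - 1
        else:
            pairs = frozenset()
            motif_text = payload if payload != _ABSENT else ""
        pred = MotifPrediction(
            record_id=rec_id,
            rank=rank,
            score=score,
            start=start,
            end=end,
            pairs=pairs,
            motif_text=motif_text,
        )
        out.setdefault(rec_id, []).append(pred)
    return out


def write_predictions(
    preds: Iterable[MotifPrediction], path, structures: dict | None = None
) -> None:
    """Write predictions in the interchange format.

    ``structures`` optionally maps ``(record_id, rank)`` to a motif-local
    dot-bracket string; otherwise the pair set is written via a local
    reconstruction when coordinates are present, or the motif text is used.
    """
    from pathlib import Path

    from .core import SecondaryStructure

    lines = []
    for p in preds:
        if structures and (p.record_id, p.rank) in structures:
            payload = structures[(p.record_id, p.rank)]
        elif p.resolved and p.pairs:
            offset = p.start - 1
            local = SecondaryStructure(
                p.end - p.start + 1,
                frozenset(q.shifted(-offset, -offset) for q in p.pairs),
            )
            payload = local.to_dbn()
        elif p.motif_text:
            payload = p.motif_text
        else:
            payload = _ABSENT
        lines.append(
            _FIELD_SEP.join(
                [
                    p.record_id,
                    str(p.rank),
                    str(p.score),
                    str(p.start) if p.start is not None else _ABSENT,
                    str(p.end) if p.end is not None else _ABSENT,
                    payload,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
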