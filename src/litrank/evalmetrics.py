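"""Retrieval evaluation: precision/recall/F, AP, precision at k, PR curves.

Set-level metrics treat the retrieved list as an unordered set against a
gold standard; rank-level metrics (average precision, precision at k, the
precision/recall curve) reward putting relevant genes early.  Conventions:

* F-measure is the harmonic mean 2pr/(p+r); any zero denominator yields 0
  (flagged) rather than NaN so batch evaluation never propagates NaNs.
* Average precision divides by the total gold size R, standard IR usage:
  relevant genes missing from the ranking contribute zero, so a method is
  penalized for what it fails to retrieve, not only for ordering.
* Precision at k divides by k even when the ranking is shorter, keeping
  the metric comparable across methods of different list length; pass
  ``short_list_denominator="length"`` for the min(k, len) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Sequence, Union

from .goldstd import GoldStandard
from .prioritize import RankedList

Ranking = Union[RankedList, Sequence[int]]


@dataclass(frozen=True)
class EvalReport:
    """Bundle of retrieval-quality metrics for one query.

    ``precision = overlap/retrieved`` and ``recall = overlap/relevant``
    whenever the denominators are nonzero; ``f_measure = 2pr/(p+r)`` when
    p + r > 0, else 0 with ``degenerate`` set.
    """

    precision: float
    recall: float
    f_measure: float
    retrieved_count: int
    relevant_count: int
    overlap_count: int
    degenerate: bool = False
    ap: float | None = None
    precision_at: dict[int, float] = field(default_factory=dict)
    pr_curve: tuple[tuple[float, float], ...] = ()

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "retrieved_count": self.retrieved_count,
            "relevant_count": self.relevant_count,
            "overlap_count": self.overlap_count,
            "degenerate": self.degenerate,
        }
        if self.ap is not None:
            out["ap"] = self.ap
        for k, v in sorted(self.precision_at.items()):
            out[f"precision_at_{k}"] = v
        return out


def _gene_sequence(ranking: Ranking) -> list[int]:
    if isinstance(ranking, RankedList):
        return ranking.gene_ids()
    return list(ranking)


def _gold_set(gold: GoldStandard | Iterable[int]) -> frozenset[int]:
    if isinstance(gold, GoldStandard):
        return gold.gene_ids
    return frozenset(gold)


def report_from_counts(retrieved_count: int, relevant_count: int, overlap_count: int) -> EvalReport:
    """Precision/recall/F from bare counts (e.g. a published summary table)."""
    if overlap_count > min(retrieved_count, relevant_count):
        raise ValueError("overlap cannot exceed either set size")
    degenerate = retrieved_count == 0 or relevant_count == 0
    p = overlap_count / retrieved_count if retrieved_count else 0.0
    r = overlap_count / relevant_count if relevant_count else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    if (p + r) == 0:
        degenerate = True
    return EvalReport(
        precision=p,
        recall=r,
        f_measure=f,
        retrieved_count=retrieved_count,
        relevant_count=relevant_count,
        overlap_count=overlap_count,
        degenerate=degenerate,
    )


def precision_recall_f(retrieved: Iterable[int], gold: GoldStandard | Iterable[int]) -> EvalReport:
    """Set-level precision, recall and F-measure of a retrieved gene set."""
    rset = frozenset(retrieved)
    gset = _gold_set(gold)
    return report_from_counts(len(rset), len(gset), len(rset & gset))


def average_precision(ranking: Ranking, gold: GoldStandard | Iterable[int]) -> float:
    """Average precision: mean of precision at each relevant rank, over R.

    AP = (1/R) * sum over ranks r where the entry is relevant of
    precision@r, with R the gold-set size.  Relevant genes absent from
    the ranking contribute 0.

    Raises
    ------
    ValueError
        If the gold set is empty (AP undefined).
    """
    gset = _gold_set(gold)
    if not gset:
        raise ValueError("average precision is undefined for an empty gold standard")
    hits = 0
    total = 0.0
    for rank, gene in enumerate(_gene_sequence(ranking), start=1):
        if gene in gset:
            hits += 1
            total += hits / rank
    return total / len(gset)


def precision_at_k(
    ranking: Ranking,
    gold: GoldStandard | Iterable[int],
    k: int,
    short_list_denominator: Literal["k", "length"] = "k",
) -> float:
    """Fraction of the top-k ranked genes that are in the gold standard.

    For rankings shorter than k the default denominator stays k; the
    ``"length"`` convention divides by min(k, len) instead.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    genes = _gene_sequence(ranking)
    gset = _gold_set(gold)
    hits = sum(1 for g in genes[:k] if g in gset)
    denom = k if short_list_denominator == "k" else min(k, len(genes)) or k
    return hits / denom


def pr_curve(ranking: Ranking, gold: GoldStandard | Iterable[int]) -> list[tuple[float, float]]:
    """Precision/recall pairs at every rank prefix 1..len.

    Recall is non-decreasing along the list; the final point's recall
    equals the set-level recall of the full ranking.

    Raises
    ------
    ValueError
        If the gold set is empty.
    """
    gset = _gold_set(gold)
    if not gset:
        raise ValueError("PR curve is undefined for an empty gold standard")
    points = []
    hits = 0
    for rank, gene in enumerate(_gene_sequence(ranking), start=1):
        if gene in gset:
            hits += 1
        points.append((hits / len(gset), hits / rank))
    return points


def evaluate_ranking(
    ranking: Ranking,
    gold: GoldStandard | Iterable[int],
    at_k: Sequence[int] = (50, 100),
) -> EvalReport:
    """Full report for a ranked list: set metrics plus AP, P@k and the curve."""
    genes = _gene_sequence(ranking)
    base = precision_recall_f(genes, gold)
    gset = _gold_set(gold)
    ap = average_precision(genes, gset) if gset else None
    curve = tuple(pr_curve(genes, gset)) if gset else ()
    p_at = {k: precision_at_k(genes, gset, k) for k in at_k}
    return EvalReport(
        precision=base.precision,
        recall=base.recall,
        f_measure=base.f_measure,
        retrieved_count=base.retrieved_count,
        relevant_count=base.relevant_count,
        overlap_count=base.overlap_count,
        degenerate=base.degenerate,
        ap=ap,
        precision_at=p_at,
        pr_curve=curve,
    )


def threshold_fold(before: EvalReport, after: EvalReport) -> float:
    """F-measure fold change of thresholding: after.F / before.F.

    Raises
    ------
    ValueError
        If the pre-threshold F-measure is zero (fold undefined).
    """
    if before.f_measure == 0:
        raise ValueError("fold change undefined: pre-threshold F-measure is zero")
    return after.f_measure / before.f_measure


def write_report_csv(report: EvalReport, stream: IO[str]) -> None:
    """Serialize a report as flat key/value CSV."""
    stream.write("metric,value\n")
    for key, value in report.as_dict().items():
        stream.write(f"{key},{value}\n")


def write_pr_curve_tsv(curve: Sequence[tuple[float, float]], stream: IO[str]) -> None:
    """Two-column TSV (recall, precision) for plotting."""
    stream.write("recall\tprecision\n")
    for recall, precision in curve:
        stream.write(f"{recall!r}\t{precision!r}\n")
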