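"""Gene scoring and ranking.

Given a query's publication hits and a gene-to-publication link table,
each gene with at least one supporting hit is scored and ranked.  Two
methods are provided:

``counts``
    The score is simply ``j``, the gene's total publication count in the
    link table — the convention common to count-based retrieval tools.
    It favours well-studied genes regardless of the query.

``hypergeometric``
    The score is ``S_G = -log10 f(m, n, j, k)`` where ``f`` is the upper
    tail of the hypergeometric distribution:

        f(m, n, j, k) = sum_{i=k}^{min(n,j)} C(j,i) C(m-j, n-i) / C(m,n)

    with ``m`` publications in the table, ``n`` of them query-relevant,
    ``j`` linked to the gene and ``k`` both query-relevant and linked to
    the gene.  ``f`` is the probability of seeing ``k`` or more
    query-relevant publications for the gene by chance, so a small tail
    (large score) marks a gene cited in the query literature far more
    often than its overall publication volume predicts.  This corrects
    the popularity bias of raw counts.

The tail is evaluated in log space (log-binomials from log-gamma,
accumulated against the maximum term), since ``m`` can reach ~6.5e5 and
direct binomial coefficients overflow long before that.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import IO, Literal, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .linktable import LinkTable
from .retrieval import PmidSet

#: Default score threshold: score < 2 corresponds to p > 0.01.
DEFAULT_THRESHOLD = 2.0

#: Default cap on -log10(p): p-values below 1e-308 (the edge of double
#: precision normals) are clamped so scores stay finite.
DEFAULT_MAX_SCORE = 308.0

Method = Literal["counts", "hypergeometric"]

CSV_COLUMNS = ["rank", "gene_id", "method", "score", "p_value", "k", "j", "supporting_pmids"]


@dataclass(frozen=True)
class QueryContext:
    """The joined quantities feeding both scoring methods.

    Attributes
    ----------
    m : int
        Distinct publications in the link table.
    n : int
        Query-relevant publications: retrieved PMIDs that are present in
        the table.
    evidence : dict[int, tuple[int, int, tuple[int, ...]]]
        ``gene_id -> (j, k, supporting_pmids)`` for every gene with
        ``k >= 1``; supporting PMIDs are sorted descending (PMIDs grow
        with time, so descending order is most-recent-first).
    query_label : str
    """

    m: int
    n: int
    evidence: dict[int, tuple[int, int, tuple[int, ...]]]
    query_label: str = ""


@dataclass(frozen=True)
class GeneScore:
    """One scored gene: the score, its evidence counts and support."""

    gene_id: int
    score: float
    p_value: Optional[float]
    k: int
    j: int
    supporting_pmids: tuple[int, ...]


@dataclass(frozen=True)
class RankedList:
    """Scored genes in rank order (scores non-increasing, ties broken
    by descending ``k`` then ascending gene ID)."""

    method: Method
    entries: tuple[GeneScore, ...]
    context: QueryContext
    threshold_applied: Optional[float] = None

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[int]:
        return [e.gene_id for e in self.entries]


def build_query_context(table: LinkTable, query: PmidSet) -> QueryContext:
    """Join a query's PMIDs with the link table.

    ``n`` counts only retrieved PMIDs that occur in the table; the
    evidence map lists exactly the genes with at least one query-relevant
    publication, each carrying its full ``j`` from the whole table.  An
    empty intersection is valid and yields empty evidence.
    """
    table_pmids = table.publications()
    relevant = query.pmids & table_pmids
    evidence: dict[int, tuple[int, int, tuple[int, ...]]] = {}
    for gene, pmids in table.pmids_by_gene().items():
        support = pmids & relevant
        if support:
            evidence[gene] = (
                len(pmids),
                len(support),
                tuple(sorted(support, reverse=True)),
            )
    return QueryContext(
        m=len(table_pmids),
        n=len(relevant),
        evidence=evidence,
        query_label=query.query_label,
    )


def _log_binom(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(m: int, n: int, j: int, k: int) -> float:
    """Upper hypergeometric tail ``f(m, n, j, k)``.

    Probability of observing ``k`` or more query-relevant publications
    for a gene with ``j`` of the table's ``m`` publications when ``n``
    are query-relevant.  Computed stably in log space; the result is in
    ``(0, 1]`` (``k = 0`` returns exactly 1: the full mass).

    Raises
    ------
    ValueError
        If the arguments violate ``0 <= k <= min(n, j) <= m``, ``n <= m``
        or ``j <= m``.
    """
    if not (0 <= n <= m and 0 <= j <= m):
        raise ValueError(f"need 0 <= n, j <= m; got m={m}, n={n}, j={j}")
    upper = min(n, j)
    if not (0 <= k <= upper):
        raise ValueError(f"need 0 <= k <= min(n, j) = {upper}; got k={k}")
    # the overlap cannot fall below n + j - m, so the tail there is the
    # full mass: exactly 1
    lower = max(0, n + j - m)
    if k <= lower:
        return 1.0
    i = np.arange(k, upper + 1, dtype=np.float64)
    log_terms = _log_binom(float(j), i) + _log_binom(float(m - j), float(n) - i) - _log_binom(
        float(m), float(n)
    )
    log_p = float(logsumexp(log_terms))
    # Accumulated rounding can push the sum a hair above 1 when k is far
    # into the bulk; clamp into (0, 1].
    return min(math.exp(log_p), 1.0) if log_p < 0 else 1.0


def score_genes(
    context: QueryContext,
    method: Method = "hypergeometric",
    max_score: float = DEFAULT_MAX_SCORE,
    count_by: Literal["j", "k"] = "j",
) -> RankedList:
    """Score every evidenced gene and return the ranked list.

    Parameters
    ----------
    context : QueryContext
    method : {"hypergeometric", "counts"}
        ``hypergeometric`` assigns ``S_G = -log10 f(m, n, j, k)``;
        ``counts`` assigns the gene's publication count.
    max_score : float
        Cap on the hypergeometric score; p-values below ``10**-max_score``
        are clamped (the tail is unbounded in principle).
    count_by : {"j", "k"}
        For the counts method: score by the gene's total publication
        count ``j`` (default) or by its query-relevant count ``k``, the
        convention some other tools use.

    Genes with ``k = 0`` never appear: only retrieved genes are ranked.
    """
    if method not in ("counts", "hypergeometric"):
        raise ValueError(f"unknown method {method!r}")
    if count_by not in ("j", "k"):
        raise ValueError(f"count_by must be 'j' or 'k', got {count_by!r}")
    entries = []
    min_p = 10.0 ** (-max_score)
    for gene_id, (j, k, support) in context.evidence.items():
        if method == "hypergeometric":
            p = hypergeom_tail(context.m, context.n, j, k)
            score = -math.log10(max(p, min_p))
            entries.append(GeneScore(gene_id, score, p, k, j, support))
        else:
            score = float(j if count_by == "j" else k)
            entries.append(GeneScore(gene_id, score, None, k, j, support))
    entries.sort(key=lambda e: (-e.score, -e.k, e.gene_id))
    return RankedList(method=method, entries=tuple(entries), context=context)


def apply_threshold(ranking: RankedList, min_score: float = DEFAULT_THRESHOLD) -> RankedList:
    """Drop entries scoring below ``min_score``; order is preserved.

    The boundary is kept: a hypergeometric score of exactly 2 (p exactly
    0.01) survives the default threshold, since removal targets
    score < 2 / p > 0.01 strictly.
    """
    if min_score < 0:
        raise ValueError(f"min_score must be non-negative, got {min_score}")
    kept = tuple(e for e in ranking.entries if e.score >= min_score)
    return replace(ranking, entries=kept, threshold_applied=min_score)


def write_ranking_csv(ranking: RankedList, stream: IO[str], max_pmids: Optional[int] = None) -> None:
    """Write a ranking as CSV (RFC 4180): one row per gene.

    Columns: rank, gene_id, method, score, p_value (empty for counts),
    k, j, supporting_pmids (semicolon-separated, descending PMID).
    ``max_pmids`` truncates the supporting-publication list for display.
    Scores and p-values are written in full ``repr`` precision so the
    file round-trips bit-exactly.
    """
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for rank, e in enumerate(ranking.entries, start=1):
        pmids = e.supporting_pmids[:max_pmids] if max_pmids is not None else e.supporting_pmids
        writer.writerow(
            [
                rank,
                e.gene_id,
                ranking.method,
                repr(e.score),
                "" if e.p_value is None else repr(e.p_value),
                e.k,
                e.j,
                ";".join(str(p) for p in pmids),
            ]
        )


def read_ranking_csv(stream: IO[str]) -> RankedList:
    """Re-parse a CSV written by :func:`write_ranking_csv`.

    The reconstructed context carries only what the file stores (m and n
    are unknown: zeros).  Intended for the evaluate stage and round-trip
    checks.
    """
    reader = csv.DictReader(stream)
    entries = []
    method: Method = "hypergeometric"
    for row in reader:
        method = row["method"]  # type: ignore[assignment]
        pmids = tuple(int(t) for t in row["supporting_pmids"].split(";") if t)
        entries.append(
            GeneScore(
                gene_id=int(row["gene_id"]),
                score=float(row["score"]),
                p_value=float(row["p_value"]) if row["p_value"] else None,
                k=int(row["k"]),
                j=int(row["j"]),
                supporting_pmids=pmids,
            )
        )
    ctx = QueryContext(m=0, n=0, evidence={})
    return RankedList(method=method, entries=tuple(entries), context=ctx)
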