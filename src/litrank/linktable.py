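"""Gene-to-publication link tables.

The link table is the universe for everything downstream: a bipartite
mapping between Entrez-Gene IDs and PubMed IDs (the NCBI ``gene2pubmed``
dialect: tab-separated ``tax_id``, ``GeneID``, ``PubMed_ID`` columns with
an optional ``#``-prefixed header).  This module reads, filters and
summarizes such tables.  Two numbers computed here feed the scoring stage:
``m``, the number of distinct publications in the table, and ``j``, the
number of publications linked to a given gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

#: Default promiscuity cap: publications linked to more than this many
#: distinct genes are considered unspecific and removed.
DEFAULT_PROMISCUITY_CAP = 500

#: Fraction of malformed lines above which parsing fails outright.
MALFORMED_FRACTION_LIMIT = 0.10


class LinkTableParseError(ValueError):
    """Raised when a gene2pubmed stream cannot be parsed."""


@dataclass(frozen=True, order=True)
class LinkRecord:
    """One association between a gene and a publication.

    Attributes
    ----------
    tax_id : int
        NCBI taxonomy identifier of the gene's species.
    gene_id : int
        Entrez-Gene identifier.
    pmid : int
        PubMed identifier of the supporting publication.
    """

    tax_id: int
    gene_id: int
    pmid: int

    def __post_init__(self) -> None:
        if self.tax_id <= 0 or self.gene_id <= 0 or self.pmid <= 0:
            raise ValueError(
                f"LinkRecord fields must be positive integers, got "
                f"({self.tax_id}, {self.gene_id}, {self.pmid})"
            )


@dataclass
class LinkTable:
    """A deduplicated set of gene-publication links.

    Records are keyed on ``(gene_id, pmid)``: in NCBI data a gene belongs
    to a single taxon, so a duplicated pair differing only in ``tax_id``
    is a file artifact and is collapsed.

    Attributes
    ----------
    records : frozenset[LinkRecord]
        The deduplicated association set.
    promiscuity_cap : int or None
        If not None, :func:`filter_promiscuous` has been applied with this
        cap, and every publication links at most this many distinct genes.
    tax_filter : frozenset[int] or None
        Taxonomy restriction applied at load time, if any.
    """

    records: frozenset[LinkRecord] = field(default_factory=frozenset)
    promiscuity_cap: Optional[int] = None
    tax_filter: Optional[frozenset[int]] = None

    def __len__(self) -> int:
        return len(self.records)

    def publications(self) -> frozenset[int]:
        """Distinct PMIDs present in the table."""
        return frozenset(r.pmid for r in self.records)

    def genes(self) -> frozenset[int]:
        """Distinct gene IDs present in the table."""
        return frozenset(r.gene_id for r in self.records)

    def pmids_by_gene(self) -> dict[int, frozenset[int]]:
        """Map each gene to the set of publications linked to it."""
        out: dict[int, set[int]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, set()).add(r.pmid)
        return {g: frozenset(p) for g, p in out.items()}

    def genes_by_pmid(self) -> dict[int, frozenset[int]]:
        """Map each publication to the set of genes it is linked to."""
        out: dict[int, set[int]] = {}
        for r in self.records:
            out.setdefault(r.pmid, set()).add(r.gene_id)
        return {p: frozenset(g) for p, g in out.items()}


@dataclass(frozen=True)
class TableStats:
    """Summary counts of a link table.

    ``m`` is the distinct-publication count (the population size of the
    hypergeometric test); ``j_by_gene`` maps each gene to its publication
    count ``j``.
    """

    m: int
    gene_count: int
    j_by_gene: Mapping[int, int]


def _parse_line(line: str, lineno: int) -> Optional[tuple[int, int, int]]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise LinkTableParseError(
            f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
        )
    try:
        return int(parts[0]), int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise LinkTableParseError(
            f"line {lineno}: non-integer field in {parts[:3]!r}"
        ) from exc


def read_gene2pubmed(
    stream: IO[str] | Iterable[str],
    tax_filter: Optional[Iterable[int]] = None,
    strict: bool = False,
) -> LinkTable:
    """Read a gene2pubmed-dialect TSV into a :class:`LinkTable`.

    Lines beginning with ``#`` (the NCBI commented header) and blank lines
    are skipped.  Malformed lines are skipped with a warning unless
    ``strict`` is true; parsing fails if more than 10% of data lines are
    malformed.

    Parameters
    ----------
    stream
        Text lines in ``tax_id<TAB>GeneID<TAB>PubMed_ID`` form.
    tax_filter
        If given, rows whose ``tax_id`` is not in this set are dropped
        (e.g. ``{9606}`` restricts to human genes).
    strict
        If true, raise on the first malformed line instead of skipping.

    Returns
    -------
    LinkTable
        Deduplicated table; empty input yields an empty table.
    """
    taxa = frozenset(tax_filter) if tax_filter is not None else None
    seen: dict[tuple[int, int], LinkRecord] = {}
    n_data = 0
    n_bad = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n_data += 1
        try:
            tax_id, gene_id, pmid = _parse_line(raw, lineno)
            rec = LinkRecord(tax_id, gene_id, pmid)
        except (LinkTableParseError, ValueError) as exc:
            if strict:
                if isinstance(exc, LinkTableParseError):
                    raise
                raise LinkTableParseError(f"line {lineno}: {exc}") from exc
            n_bad += 1
            logger.warning("skipping malformed gene2pubmed line %d: %s", lineno, exc)
            continue
        if taxa is not None and rec.tax_id not in taxa:
            continue
        seen.setdefault((rec.gene_id, rec.pmid), rec)
    if n_bad:
        logger.warning("gene2pubmed: skipped %d malformed of %d data lines", n_bad, n_data)
        if n_data and n_bad / n_data > MALFORMED_FRACTION_LIMIT:
            raise LinkTableParseError(
                f"{n_bad}/{n_data} lines malformed (> {MALFORMED_FRACTION_LIMIT:.0%})"
            )
    return LinkTable(records=frozenset(seen.values()), tax_filter=taxa)


def write_gene2pubmed(table: LinkTable, stream: IO[str], header: bool = True) -> None:
    """Write a table back out in the gene2pubmed dialect (round-trip writer)."""
    if header:
        stream.write("#tax_id\tGeneID\tPubMed_ID\n")
    for rec in sorted(table.records):
        stream.write(f"{rec.tax_id}\t{rec.gene_id}\t{rec.pmid}\n")


def filter_promiscuous(table: LinkTable, cap: int = DEFAULT_PROMISCUITY_CAP) -> LinkTable:
    """Remove publications linked to more than ``cap`` distinct genes.

    Such publications (large-scale surveys, genome papers) lack
    specificity and would dominate every query.  The inequality is
    strict: a publication linked to exactly ``cap`` genes is retained.

    Parameters
    ----------
    table : LinkTable
    cap : int
        Maximum allowed distinct-gene degree per publication (default 500).

    Returns
    -------
    LinkTable
        New table with ``promiscuity_cap`` recorded.
    """
    if cap < 1:
        raise ValueError(f"promiscuity cap must be >= 1, got {cap}")
    degree = table.genes_by_pmid()
    drop = {p for p, genes in degree.items() if len(genes) > cap}
    if drop:
        logger.info("promiscuity filter: removing %d publications (> %d genes)", len(drop), cap)
    kept = frozenset(r for r in table.records if r.pmid not in drop)
    return LinkTable(records=kept, promiscuity_cap=cap, tax_filter=table.tax_filter)


def table_stats(table: LinkTable) -> TableStats:
    """Materialize the counts the scoring stage needs (``m`` and per-gene ``j``)."""
    j_by_gene = {g: len(p) for g, p in table.pmids_by_gene().items()}
    return TableStats(
        m=len(table.publications()),
        gene_count=len(j_by_gene),
        j_by_gene=j_by_gene,
    )
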