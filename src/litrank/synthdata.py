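"""Synthetic corpora with planted relevant genes.

The generator builds a miniature literature: a gene-to-publication link
table, a query publication set, and a planted "truly relevant" gene set
serving as the gold standard.  Publications cite a Poisson-distributed
number of genes (shifted so every publication cites at least one);
publications belonging to the query cite planted genes with probability
scaled up by an enrichment factor, which directly controls the k/n versus
j/m contrast the hypergeometric test detects.  Enrichment 1 is the null:
planted and background genes are exchangeable.  Optional promiscuous
publications (linked to more genes than the specificity cap allows)
exercise the promiscuity filter.

All randomness flows from the single seed in the spec; there is no global
random state, so a spec regenerates byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .goldstd import GoldStandard, write_gene_list
from .linktable import DEFAULT_PROMISCUITY_CAP, LinkRecord, LinkTable, write_gene2pubmed
from .retrieval import PmidSet, write_pmid_list

#: PMIDs start here so synthetic IDs look like modern PubMed IDs and
#: never collide with small gene IDs in hand-written fixtures.
PMID_BASE = 1_000_000


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Attributes
    ----------
    seed : int
        Sole source of randomness.
    n_genes, n_pubs : int
        Universe sizes (gene IDs 1..n_genes; PMIDs consecutive from
        ``PMID_BASE + 1``).
    n_query_pubs : int
        How many publications the query matches.
    n_planted : int
        Size of the planted relevant-gene set (the gold standard).
    mean_genes_per_pub : float
        Mean of the shifted-Poisson gene count per publication (min 1).
    enrichment : float
        Multiplier (>= 1) on a planted gene's probability of being cited
        by a query publication; 1 means no signal.
    promiscuous_pubs : int
        Number of extra publications each linked to more genes than the
        default specificity cap (they should be removed by the filter).
    tax_id : int
        Taxonomy ID stamped on every record.
    """

    seed: int
    n_genes: int = 200
    n_pubs: int = 1000
    n_query_pubs: int = 100
    n_planted: int = 20
    mean_genes_per_pub: float = 5.0
    enrichment: float = 8.0
    promiscuous_pubs: int = 0
    tax_id: int = 9606

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_pubs < 1:
            raise ValueError("n_genes and n_pubs must be positive")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if self.n_query_pubs > self.n_pubs:
            raise ValueError("n_query_pubs cannot exceed n_pubs")
        if self.mean_genes_per_pub <= 0:
            raise ValueError("mean_genes_per_pub must be positive")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.promiscuous_pubs < 0:
            raise ValueError("promiscuous_pubs must be non-negative")
        if self.promiscuous_pubs and self.n_genes <= DEFAULT_PROMISCUITY_CAP:
            raise ValueError(
                f"promiscuous publications need more than {DEFAULT_PROMISCUITY_CAP} genes; "
                f"spec has n_genes={self.n_genes}"
            )


def generate_corpus(spec: CorpusSpec) -> tuple[LinkTable, PmidSet, GoldStandard]:
    """Generate (link table, query PMID set, planted gold standard).

    Ordinary publications cite between 1 and the specificity cap genes,
    so the promiscuity filter removes exactly the deliberately
    over-linked publications.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = np.arange(1, spec.n_genes + 1)
    pmids = np.arange(PMID_BASE + 1, PMID_BASE + 1 + spec.n_pubs)

    planted = np.sort(rng.choice(genes, size=spec.n_planted, replace=False))
    planted_set = frozenset(int(g) for g in planted)
    query_pmids = np.sort(rng.choice(pmids, size=spec.n_query_pubs, replace=False))
    query_set = frozenset(int(p) for p in query_pmids)

    weights = np.ones(spec.n_genes)
    weights[planted - 1] = spec.enrichment
    enriched_p = weights / weights.sum()

    max_degree = min(spec.n_genes, DEFAULT_PROMISCUITY_CAP)
    records: list[LinkRecord] = []
    for pmid in pmids:
        count = 1 + rng.poisson(spec.mean_genes_per_pub - 1)
        count = int(min(count, max_degree))
        p = enriched_p if int(pmid) in query_set else None
        cited = rng.choice(genes, size=count, replace=False, p=p)
        records.extend(LinkRecord(spec.tax_id, int(g), int(pmid)) for g in cited)

    # Over-linked publications: degree strictly above the cap.
    for extra in range(spec.promiscuous_pubs):
        pmid = PMID_BASE + spec.n_pubs + 1 + extra
        degree = int(DEFAULT_PROMISCUITY_CAP + 1 + rng.integers(0, min(50, spec.n_genes - DEFAULT_PROMISCUITY_CAP)))
        cited = rng.choice(genes, size=degree, replace=False)
        records.extend(LinkRecord(spec.tax_id, int(g), pmid) for g in cited)

    table = LinkTable(records=frozenset(records))
    query = PmidSet(
        pmids=query_set,
        declared_count=len(query_set),
        query_label=f"synthetic query (seed={spec.seed})",
    )
    gold = GoldStandard(
        label=f"planted genes (seed={spec.seed})",
        gene_ids=planted_set,
        provenance=(f"synthetic corpus seed={spec.seed}, enrichment={spec.enrichment}",),
    )
    return table, query, gold


def write_corpus(
    spec: CorpusSpec, out_dir: str | os.PathLike
) -> tuple[Path, Path, Path]:
    """Generate a corpus and write it as consumable fixture files.

    Writes ``links.tsv`` (gene2pubmed dialect), ``query_pmids.txt`` and
    ``gold_genes.txt`` under ``out_dir``; returns the three paths.
    """
    table, query, gold = generate_corpus(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    links = out / "links.tsv"
    qfile = out / "query_pmids.txt"
    gfile = out / "gold_genes.txt"
    with open(links, "w") as fh:
        write_gene2pubmed(table, fh)
    with open(qfile, "w") as fh:
        write_pmid_list(query, fh)
    with open(gfile, "w") as fh:
        write_gene_list(gold, fh)
    return links, qfile, gfile
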