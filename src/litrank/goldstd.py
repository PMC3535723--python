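"""Gold-standard relevant-gene sets.

Evaluation of a retrieved gene list needs a curated set of "truly
relevant" genes.  Three builders are provided, mirroring the public
databases this kind of benchmark draws on:

* Gene Ontology: a term's gene set is every gene annotated to the term
  *or to any of its descendants* in the GO DAG (the true-path rule —
  granular annotations propagate to parent terms).
* OMIM: a user-selected set of MIM numbers is mapped to Entrez-Gene IDs
  through the ``mim2gene`` file.
* Plain gene-ID lists (e.g. exported from GAD), merged by set union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relationship types across which annotations propagate by default.
#: GO's true-path rule holds over both is_a and part_of.
DEFAULT_PROPAGATION_RELS = ("is_a", "part_of")


class OboCycleError(ValueError):
    """Raised when the propagation edges of an ontology contain a cycle."""


class UnknownTermError(KeyError):
    """Raised when a requested term is absent from the DAG."""


@dataclass
class GoDag:
    """A Gene Ontology DAG restricted to the propagation relationships.

    Attributes
    ----------
    terms : frozenset[str]
        Non-obsolete term IDs.
    names : dict[str, str]
        Term ID -> label.
    parents : dict[str, frozenset[str]]
        Term -> parents via the declared relationship types.
    obsolete : frozenset[str]
        Obsolete term IDs (excluded from ``terms`` and from propagation).
    relationships : tuple[str, ...]
        The edge types that propagate annotations.
    """

    terms: frozenset[str]
    names: dict[str, str]
    parents: dict[str, frozenset[str]]
    obsolete: frozenset[str] = field(default_factory=frozenset)
    relationships: tuple[str, ...] = DEFAULT_PROPAGATION_RELS

    def children(self) -> dict[str, set[str]]:
        """Invert the parent map."""
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                out.setdefault(p, set()).add(child)
        return out

    def descendants(self, term: str) -> frozenset[str]:
        """The term plus every term reachable downward from it."""
        if term not in self.terms:
            raise UnknownTermError(term)
        kids = self.children()
        seen = {term}
        stack = [term]
        while stack:
            for c in kids.get(stack.pop(), ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)


@dataclass(frozen=True)
class GoldStandard:
    """A labelled relevant-gene set with provenance."""

    label: str
    gene_ids: frozenset[int]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GoldStandard label must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


def parse_obo(
    stream: IO[str] | str,
    relationships: Sequence[str] = DEFAULT_PROPAGATION_RELS,
) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag`.

    Only the declared ``relationships`` become propagation edges (default
    ``is_a`` and ``part_of``; pass ``("is_a",)`` to restrict).  Obsolete
    terms are flagged and excluded from propagation.  Parents referencing
    terms absent from the file are reported as warnings and dropped.

    Raises
    ------
    OboCycleError
        If the propagation edges contain a cycle (names one cycle).
    """
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    obsolete = frozenset(
        t for t, data in graph.nodes(data=True) if data.get("is_obsolete") in ("true", True)
    )
    terms = frozenset(t for t in graph.nodes if t not in obsolete)
    names = {
        t: data.get("name", "") for t, data in graph.nodes(data=True) if t not in obsolete
    }
    rels = set(relationships)
    parents: dict[str, set[str]] = {}
    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    # obonet edges run child -> parent, keyed by relationship type.
    for child, parent, rel in graph.edges(keys=True):
        if rel not in rels or child in obsolete or parent in obsolete:
            continue
        if parent not in terms:
            logger.warning("dangling parent %s referenced by %s; dropped", parent, child)
            continue
        parents.setdefault(child, set()).add(parent)
        dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OboCycleError(f"cycle in ontology propagation edges: {path}")
    return GoDag(
        terms=terms,
        names=names,
        parents={t: frozenset(p) for t, p in parents.items()},
        obsolete=obsolete,
        relationships=tuple(relationships),
    )


def _near_matches(dag: GoDag, term: str, limit: int = 5) -> list[str]:
    token = term.lower()
    hits = [
        f"{t} ({name})"
        for t, name in sorted(dag.names.items())
        if token in t.lower() or token in name.lower()
    ]
    return hits[:limit]


def read_gene2go(
    stream: IO[str] | Iterable[str],
    tax_filter: Optional[Iterable[int]] = None,
) -> dict[str, set[int]]:
    """Read gene2go-dialect TSV lines into ``term -> direct gene set``.

    Columns by position: tax_id, GeneID, GO_ID.  Lines starting with
    ``#`` are headers; malformed lines are skipped with a warning.
    Evidence codes, when present in later columns, are not filtered.
    """
    taxa = frozenset(tax_filter) if tax_filter is not None else None
    direct: dict[str, set[int]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            logger.warning("gene2go line %d: fewer than 3 fields, skipped", lineno)
            continue
        try:
            tax_id, gene_id = int(parts[0]), int(parts[1])
        except ValueError:
            logger.warning("gene2go line %d: non-integer tax/gene field, skipped", lineno)
            continue
        if taxa is not None and tax_id not in taxa:
            continue
        direct.setdefault(parts[2], set()).add(gene_id)
    return direct


def build_go_gold(
    dag: GoDag,
    gene2go: IO[str] | Iterable[str],
    term: str,
    tax_filter: Optional[Iterable[int]] = None,
    label: Optional[str] = None,
) -> GoldStandard:
    """Gene set for a GO term with annotation propagation.

    The returned genes are those annotated to ``term`` or to any of its
    descendants (transitive closure over the DAG's propagation edges), so
    granular annotations count toward parent terms.

    Raises
    ------
    UnknownTermError
        If ``term`` is not in the DAG; the message lists near-matches by
        ID or label.
    """
    if term not in dag.terms:
        near = _near_matches(dag, term)
        hint = f"; near matches: {', '.join(near)}" if near else ""
        raise UnknownTermError(f"unknown term {term!r}{hint}")
    scope = dag.descendants(term)
    direct = read_gene2go(gene2go, tax_filter=tax_filter)
    genes: set[int] = set()
    for t in scope:
        genes |= direct.get(t, set())
    return GoldStandard(
        label=label or dag.names.get(term, term),
        gene_ids=frozenset(genes),
        provenance=(f"GO:{term} (+{len(scope) - 1} descendants)",),
    )


def parse_mim2gene(
    stream: IO[str] | Iterable[str],
    mim_ids: Iterable[int],
    label: str = "OMIM",
) -> GoldStandard:
    """Map a set of MIM numbers to Entrez-Gene IDs via a mim2gene table.

    Lines are ``MIM_number<TAB>GeneID<TAB>type``; a ``-`` gene field
    means no mapping exists.  Unmapped MIM numbers are reported in the
    provenance and logged.  Selecting which MIM records match a query
    (the ``%``/``#``-prefixed records with the query in the title) is the
    caller's job: this function only maps the chosen IDs.
    """
    wanted = set(mim_ids)
    genes: set[int] = set()
    mapped: set[int] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            logger.warning("mim2gene line %d: fewer than 2 fields, skipped", lineno)
            continue
        try:
            mim = int(parts[0])
        except ValueError:
            logger.warning("mim2gene line %d: non-integer MIM number, skipped", lineno)
            continue
        if mim not in wanted:
            continue
        gene_field = parts[1]
        if gene_field == "-" or not gene_field:
            continue
        try:
            genes.add(int(gene_field))
            mapped.add(mim)
        except ValueError:
            logger.warning("mim2gene line %d: non-integer GeneID %r, skipped", lineno, gene_field)
    unmapped = sorted(wanted - mapped)
    if unmapped:
        logger.warning("mim2gene: %d MIM numbers had no gene mapping: %s", len(unmapped), unmapped)
    prov = [f"OMIM: {len(mapped)} of {len(wanted)} MIM IDs mapped"]
    if unmapped:
        prov.append("unmapped MIM: " + ",".join(str(u) for u in unmapped))
    return GoldStandard(label=label, gene_ids=frozenset(genes), provenance=tuple(prov))


def merge_gold(parts: Sequence[GoldStandard], label: Optional[str] = None) -> GoldStandard:
    """Union of several gold standards (e.g. GAD merged with OMIM)."""
    if not parts:
        raise ValueError("merge_gold needs at least one part")
    genes: frozenset[int] = frozenset()
    prov: tuple[str, ...] = ()
    for p in parts:
        genes |= p.gene_ids
        prov += p.provenance or (p.label,)
    return GoldStandard(label=label or " + ".join(p.label for p in parts), gene_ids=genes, provenance=prov)


def read_gene_list(stream: IO[str] | Iterable[str], label: str = "gene list") -> GoldStandard:
    """Read a plain gene-ID list (one integer per line, ``#`` comments ok)."""
    genes: set[int] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            genes.add(int(line))
        except ValueError as exc:
            raise ValueError(f"gene list line {lineno}: expected integer, got {line!r}") from exc
    return GoldStandard(label=label, gene_ids=frozenset(genes), provenance=(label,))


def write_gene_list(gold: GoldStandard, stream: IO[str]) -> None:
    """Write a gold standard as a plain gene-ID list."""
    for g in sorted(gold.gene_ids):
        stream.write(f"{g}\n")
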