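"""Query publication sets.

A query against PubMed yields a set of PMIDs.  Offline, that set arrives
either as a saved eSearch XML response or as a plain one-PMID-per-line
text file; this module parses both into a :class:`PmidSet`.  A live
eUtilities client is deliberately out of the core: :class:`PublicationSource`
defines the contract such a client would satisfy, keeping the pipeline
hermetic and testable.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Protocol, runtime_checkable


class EsearchFormatError(ValueError):
    """Raised when an eSearch XML document lacks the expected structure."""


class PmidListParseError(ValueError):
    """Raised when a plain PMID list contains a non-integer token."""


@dataclass(frozen=True)
class PmidSet:
    """Publications matched by a query.

    Attributes
    ----------
    pmids : frozenset[int]
        Deduplicated PubMed IDs.
    declared_count : int or None
        The hit count asserted by the source document (eSearch ``Count``).
    truncated : bool
        True when ``declared_count`` exceeds the IDs actually present
        (the source returned only the first ``retmax`` hits).
    query_label : str
        Free-text description of the query.
    """

    pmids: frozenset[int] = field(default_factory=frozenset)
    declared_count: Optional[int] = None
    truncated: bool = False
    query_label: str = ""

    def __len__(self) -> int:
        return len(self.pmids)


@runtime_checkable
class PublicationSource(Protocol):
    """Contract a live publication-retrieval client satisfies.

    Any callable object mapping a query string to a :class:`PmidSet` can
    stand behind the pipeline; the core ships no network implementation.
    """

    def __call__(self, query: str) -> PmidSet: ...


def parse_esearch_xml(document: str | bytes, query_label: str = "") -> PmidSet:
    """Parse an NCBI eSearch XML result into a :class:`PmidSet`.

    The document must carry a ``Count`` element and an ``IdList``; the
    truncation flag is set when ``Count`` exceeds the number of ``Id``
    elements (retmax truncation).

    Raises
    ------
    EsearchFormatError
        On malformed XML or a missing ``Count``/``IdList``.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise EsearchFormatError(f"malformed eSearch XML: {exc}") from exc
    count_el = root.find(".//Count")
    idlist_el = root.find(".//IdList")
    if count_el is None or count_el.text is None:
        raise EsearchFormatError("eSearch XML has no Count element")
    if idlist_el is None:
        raise EsearchFormatError("eSearch XML has no IdList element")
    try:
        declared = int(count_el.text)
    except ValueError as exc:
        raise EsearchFormatError(f"non-integer Count: {count_el.text!r}") from exc
    ids = set()
    for id_el in idlist_el.findall("Id"):
        if id_el.text is None:
            continue
        try:
            ids.add(int(id_el.text))
        except ValueError as exc:
            raise EsearchFormatError(f"non-integer Id: {id_el.text!r}") from exc
    return PmidSet(
        pmids=frozenset(ids),
        declared_count=declared,
        truncated=declared > len(ids),
        query_label=query_label,
    )


def read_pmid_list(stream: IO[str] | Iterable[str], query_label: str = "") -> PmidSet:
    """Read a plain PMID list (one integer per line).

    Blank lines and ``#`` comments are allowed.  The declared count is the
    number of distinct PMIDs read, so the set is never flagged truncated.

    Raises
    ------
    PmidListParseError
        On a non-integer token, naming the offending line.
    """
    ids: set[int] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            pmid = int(line)
        except ValueError as exc:
            raise PmidListParseError(
                f"line {lineno}: expected an integer PMID, got {line!r}"
            ) from exc
        if pmid <= 0:
            raise PmidListParseError(f"line {lineno}: PMID must be positive, got {pmid}")
        ids.add(pmid)
    return PmidSet(
        pmids=frozenset(ids),
        declared_count=len(ids),
        truncated=False,
        query_label=query_label,
    )


def write_pmid_list(pmids: PmidSet, stream: IO[str]) -> None:
    """Write a PmidSet in the plain-text dialect (round-trip writer)."""
    for pmid in sorted(pmids.pmids):
        stream.write(f"{pmid}\n")
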