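import io

import pytest

from litrank.linktable import LinkRecord, LinkTable


@pytest.fixture
def tiny_table() -> LinkTable:
    """Three genes, four publications, human plus one mouse record."""
    records = [
        (9606, 101, 5001),
        (9606, 101, 5002),
        (9606, 101, 5003),
        (9606, 102, 5002),
        (9606, 102, 5004),
        (9606, 103, 5001),
        (10090, 201, 5005),
    ]
    return LinkTable(records=frozenset(LinkRecord(*r) for r in records))


@pytest.fixture
def toy_obo() -> str:
    """Five-term ontology: root A with children B (is_a), C (part_of);
    D is_a B; X is obsolete."""
    return """format-version: 1.2

[Term]
id: GO:0000001
name: root process

[Term]
id: GO:0000002
name: branch b
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: branch c
relationship: part_of GO:0000001 ! root process

[Term]
id: GO:0000004
name: leaf d
is_a: GO:0000002 ! branch b

[Term]
id: GO:0000099
name: gone
is_obsolete: true
"""


def as_stream(text: str) -> io.StringIO:
    return io.StringIO(text)
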