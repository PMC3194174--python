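"""Shared fixtures: the worked discharge-summary excerpt with its gold
entries, and small helpers for random structures."""

from __future__ import annotations

import pytest

from medcascade.docmodel import Document, Entry, parse_entries, tokenize_document

# The worked excerpt: a narrative passage (lines 55-58) and a medication
# list line (line 65).  Lines 1-54 and 59-64 are padding so that the gold
# coordinates refer to the same line numbers as the published example.
EXCERPT_LINES = {
    55: "the patient noted that he had a recurrence of this",
    56: "vague chest discomfort as he was sitting and",
    57: "talking to friends. He took a sublingual",
    58: "Nitroglycerin without relief.",
    65: "Flomax ( Tamsulosin ) 0.4 mg, po, qd,",
}

# gold annotation for the excerpt; the first record uses typographic
# quotes and loose spacing, which the reader must tolerate
EXCERPT_GOLD = (
    'm=“Nitroglycerin” 58:0 58:0 ||do=“nm”||mo=“sublingual” 57:6 57:6 '
    '||f=“nm” ||du=“nm” ||r=“vague chest discomfort” 56:0 56:2 ||ln=”narrative”\n'
    'm="flomax ( tamsulosin )" 65:0 65:3||do="0.4 mg" 65:4 65:5'
    '||mo="po" 65:6 65:6||f="qd" 65:7 65:7||du="nm"||r="nm"||ln="list"\n'
)


@pytest.fixture(scope="session")
def excerpt_text() -> str:
    n_lines = max(EXCERPT_LINES)
    return "\n".join(EXCERPT_LINES.get(i, "") for i in range(1, n_lines + 1)) + "\n"


@pytest.fixture(scope="session")
def excerpt_doc(excerpt_text) -> Document:
    return tokenize_document(excerpt_text, doc_id="excerpt")


@pytest.fixture(scope="session")
def excerpt_entries() -> list[Entry]:
    return parse_entries(EXCERPT_GOLD)
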