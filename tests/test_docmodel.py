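"""Tokenization, coordinates, sections, POS, and annotation I/O."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcascade.docmodel import (
    AnnotationFormatError,
    RegexPosTagger,
    SectionConfig,
    collect_headings,
    normalize_field_text,
    parse_entries,
    pos_tag,
    segment_sections,
    tokenize_document,
    write_entries,
)
from medcascade.synthetic import CorpusSpec, generate_corpus


@pytest.mark.parametrize(
    "line_no,token_idx,text",
    [
        (65, 0, "Flomax"), (65, 1, "("), (65, 2, "Tamsulosin"), (65, 3, ")"),
        (65, 4, "0.4"), (65, 5, "mg,"), (65, 6, "po,"), (65, 7, "qd,"),
        (57, 6, "sublingual"),
        (58, 0, "Nitroglycerin"),
        (56, 0, "vague"), (56, 2, "discomfort"),
    ],
)
def test_excerpt_coordinates(excerpt_doc, line_no, token_idx, text):
    """Whitespace tokenization reproduces the published line:token spans,
    punctuation staying attached to its token."""
    assert excerpt_doc.token_at(line_no, token_idx).text == text


def test_blank_lines_keep_their_numbers():
    doc = tokenize_document("a b\n\nc\n")
    assert doc.n_lines == 3
    assert doc.line_tokens(2) == []
    assert doc.token_at(3, 0).text == "c"
    assert tokenize_document("").n_lines == 1 and tokenize_document("").line_tokens(1) == []


@given(st.lists(st.text(alphabet=" \tabcX.,0", min_size=0, max_size=30), max_size=8))
@settings(max_examples=60, deadline=None)
def test_tokenization_reversible_up_to_whitespace(lines):
    """Joining a line's tokens with single spaces reproduces the line's
    non-whitespace content in order."""
    doc = tokenize_document("\n".join(lines))
    for i, raw in enumerate(lines, start=1):
        if i <= doc.n_lines:
            assert " ".join(t.text for t in doc.line_tokens(i)) == " ".join(raw.split())


def test_token_indices_are_line_ranks(excerpt_doc):
    for line in excerpt_doc.lines:
        assert [t.token_idx for t in line] == list(range(len(line)))


# --- headings and sections -------------------------------------------------

def test_frequent_heading_collected_infrequent_not():
    corpus = ["DISCHARGE MEDICATIONS:\nAprizol\n"] * 10 + ["ADDENDUM:\nnote\n"] * 2
    found = collect_headings(corpus, SectionConfig(heading_frequency_threshold=3))
    assert "DISCHARGE MEDICATIONS" in found
    assert "ADDENDUM" not in found


def test_lowercase_heading_never_collected():
    corpus = ["Discharge meds:\nAprizol\n"] * 10
    assert collect_headings(corpus, SectionConfig(heading_frequency_threshold=1)) == set()


def test_heading_collection_matches_regex_scan_oracle():
    """On a generated corpus, collection equals an independent line-by-line
    scan with explicit counting."""
    corpus = [d.text for d in generate_corpus(CorpusSpec(n_documents=20, seed=5))]
    config = SectionConfig(heading_frequency_threshold=3)
    counts: dict[str, int] = {}
    pattern = re.compile(r"^([A-Z][A-Z ]*?)\s*:")
    for text in corpus:
        for line in text.split("\n"):
            m = pattern.match(line)
            if m and m.group(1).strip():
                h = m.group(1).strip()
                counts[h] = counts.get(h, 0) + 1
    expected = {h for h, c in counts.items() if c > 3}
    assert collect_headings(corpus, config) == expected
    assert expected  # the generated notes do contain recurring headings


def test_section_boundaries_and_exclusion():
    text = "intro line\nmore intro\nFAMILY HISTORY:\nmother well\nnothing\n" \
           "no heading here\nstill none\nyes more\nDISCHARGE MEDICATIONS:\nAprizol\nend\nlast\n"
    doc = tokenize_document(text)
    headings = {"FAMILY HISTORY", "DISCHARGE MEDICATIONS"}
    segment_sections(doc, headings)
    assert [(s.start_line, s.end_line) for s in doc.sections] == [(1, 2), (3, 8), (9, 12)]
    assert [s.excluded for s in doc.sections] == [False, True, False]
    # sections partition the document's lines exactly once
    covered = [ln for s in doc.sections for ln in range(s.start_line, s.end_line + 1)]
    assert covered == list(range(1, doc.n_lines + 1))


def test_no_headings_yields_one_anonymous_section():
    doc = tokenize_document("just text\nmore text\n")
    segment_sections(doc, set())
    assert len(doc.sections) == 1
    assert doc.sections[0].heading == "" and not doc.sections[0].excluded
    assert (doc.sections[0].start_line, doc.sections[0].end_line) == (1, 2)


# --- POS tagging -------------------------------------------------------------

POS_ORACLE = {
    # frozen expectations from the fallback tagger's rule table
    "0.4": "CD", "25": "CD", "10:30": "CD",
    "the": "DT", "he": "PRP", "of": "IN", "was": "VBD", "and": "CC",
    "walking": "VBG", "improved": "VBD", "slowly": "RB",
    "medication": "NN", "nervous": "JJ",
    "Nitroglycerin": "NNP", "aspirin": "NN", ".": ".", "(": ".",
    "mg,": "NN",
}


def test_default_tagger_matches_rule_table_oracle():
    doc = tokenize_document(" ".join(POS_ORACLE) + "\n")
    labels = pos_tag(doc)
    got = {t.text: labels[t.coord] for t in doc.iter_tokens()}
    assert got == POS_ORACLE


def test_tagger_failure_marks_line_unk():
    def broken(tokens):
        raise RuntimeError("no model")

    doc = tokenize_document("a b\n")
    labels = pos_tag(doc, broken)
    assert set(labels.values()) == {"UNK"}


def test_empty_document_empty_label_map():
    assert pos_tag(tokenize_document("")) == {}


# --- normalization -----------------------------------------------------------

@pytest.mark.parametrize(
    "tokens,expected",
    [
        (["0.4", "mg,"], "0.4 mg"),
        (["Flomax", "(", "Tamsulosin", ")"], "flomax ( tamsulosin )"),
        (["po"], "po"),
        (["relief."], "relief"),
        ([",,"], ",,"),  # all-punctuation token kept raw
    ],
)
def test_normalize_field_text(tokens, expected):
    assert normalize_field_text(tokens) == expected


# --- annotation format -------------------------------------------------------

def test_parse_excerpt_gold(excerpt_entries):
    first, second = excerpt_entries
    assert first.name.text == "nitroglycerin"
    assert first.name.start == (58, 0) and first.name.end == (58, 0)
    assert first.mo.start == (57, 6) and first.mo.text == "sublingual"
    assert first.r.start == (56, 0) and first.r.end == (56, 2)
    assert not first.do.present and not first.f.present and not first.du.present
    assert first.ln == "narrative"
    assert second.name.start == (65, 0) and second.name.end == (65, 3)
    assert second.do.text == "0.4 mg" and second.do.start == (65, 4)
    assert second.mo.start == (65, 6) and second.f.start == (65, 7)
    assert not second.du.present and not second.r.present
    assert second.ln == "list"


def test_parsed_text_matches_normalized_span_tokens(excerpt_doc, excerpt_entries):
    """A present field's text always equals the normalization of the
    tokens its coordinates address."""
    for entry in excerpt_entries:
        for span in entry.present_fields():
            toks = excerpt_doc.tokens_in_span(span.start, span.end)
            assert normalize_field_text(toks) == span.text


def test_all_absent_non_name_slots():
    entries = parse_entries('m="aprizol" 1:0 1:0||do="nm"||mo="nm"||f="nm"||du="nm"||r="nm"||ln="list"\n')
    assert len(entries) == 1
    assert all(not getattr(entries[0], t).present for t in ("do", "mo", "f", "du", "r"))


def test_roundtrip_on_generated_records():
    """write(parse(write(E))) is the identity on synthetic gold, and the
    canonical form is a fixed point."""
    corpus = generate_corpus(CorpusSpec(n_documents=12, seed=3))
    n_records = 0
    for doc in corpus:
        text = write_entries(doc.entries)
        reparsed = parse_entries(text)
        assert reparsed == doc.entries
        assert write_entries(reparsed) == text
        n_records += len(doc.entries)
    assert n_records >= 100


@pytest.mark.parametrize(
    "record,fragment",
    [
        ('m="aprizol" 1:0 1;0||do="nm"||mo="nm"||f="nm"||du="nm"||r="nm"||ln="list"', "coordinate"),
        ('m="aprizol" 1:0 1:0||zz="nm"||do="nm"||mo="nm"||f="nm"||du="nm"||r="nm"||ln="list"', "zz"),
        ('do="5 mg" 1:0 1:1||mo="nm"||f="nm"||du="nm"||r="nm"||ln="list"', "name"),
        ('m="aprizol" 1:0 1:0||do="nm"||mo="nm"||f="nm"||du="nm"||r="nm"||ln="shelf"', "ln"),
    ],
)
def test_malformed_records_raise_with_location(record, fragment):
    with pytest.raises(AnnotationFormatError, match=fragment):
        parse_entries(record)


def test_write_requires_name():
    from medcascade.docmodel import Entry, FieldSpan

    with pytest.raises(ValueError):
        Entry.build(FieldSpan.absent("m"), "list")


def test_write_empty_collection():
    assert write_entries([]) == ""
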