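"""Feature extraction: family definitions, prefix discipline, lexicons."""

import pytest

from medcascade.docmodel import FieldSpan, tokenize_document
from medcascade.features import (
    PAD_LEFT,
    FeatureConfig,
    Lexicon,
    bucket,
    build_training_lexicon,
    extract_context_features,
    extract_token_features,
    load_external_lexicon,
)

FIXTURE_LINE = "He took a sublingual Nitroglycerin 0.4 mg today\n"  # 8 tokens


@pytest.fixture()
def fixture_doc():
    return tokenize_document(FIXTURE_LINE, doc_id="fx")


def _extract(doc, i, config, prev_tags=None, name_spans=None):
    flat = list(doc.iter_tokens())
    pos = {t.coord: "X" for t in flat}
    return extract_token_features(doc, flat, i, prev_tags or ["O"] * i, pos, config, name_spans)


def test_f1_ngrams_match_exhaustive_enumeration(fixture_doc):
    """The F1 feature set at one position equals an independently coded
    enumeration of all uni/bi/trigrams in the +/-2 window."""
    config = FeatureConfig(families=frozenset({"F1"}))
    i = 4  # "Nitroglycerin"
    feats = _extract(fixture_doc, i, config)
    words = [t.text.lower() for t in fixture_doc.iter_tokens()]
    padded = {off: (words[i + off] if 0 <= i + off < len(words) else
                    (PAD_LEFT if off < 0 else "</S>"))
              for off in range(-2, 3)}
    expected = set()
    for off in (-2, -1, 0, 1, 2):
        expected.add(f"F1:w[{off}]={padded[off]}")
    for off in (-2, -1, 0, 1):
        expected.add(f"F1:w[{off}]w[{off + 1}]={padded[off]}|{padded[off + 1]}")
    for off in (-2, -1, 0):
        expected.add(f"F1:w[{off}]w[{off + 1}]w[{off + 2}]="
                     f"{padded[off]}|{padded[off + 1]}|{padded[off + 2]}")
    assert set(feats) == expected
    assert all(v == 1.0 for v in feats.values())


def test_first_token_gets_boundary_padding(fixture_doc):
    config = FeatureConfig(families=frozenset({"F1", "F3"}))
    feats = _extract(fixture_doc, 0, config, prev_tags=[])
    assert f"F1:w[-1]={PAD_LEFT}" in feats
    assert f"F3:t[-1]={PAD_LEFT}" in feats


def test_family_prefix_discipline(fixture_doc):
    """Disabling a family removes exactly the features carrying its
    prefix, and nothing else."""
    lex = Lexicon.from_names("train", ["nitroglycerin"])
    full = FeatureConfig(families=frozenset({"F1", "F2", "F3", "F4a"}), train_lexicon=lex)
    all_feats = _extract(fixture_doc, 4, full, prev_tags=["O"] * 4)
    for family in ("F1", "F2", "F3", "F4a"):
        reduced_config = FeatureConfig(
            families=full.families - {family}, train_lexicon=lex)
        reduced = _extract(fixture_doc, 4, reduced_config, prev_tags=["O"] * 4)
        removed = set(all_feats) - set(reduced)
        assert removed == {k for k in all_feats if k.startswith(family + ":")}
        assert set(reduced) <= set(all_feats)


def test_extraction_is_deterministic(fixture_doc):
    lex = Lexicon.from_names("train", ["nitroglycerin", "0.4 mg"])
    config = FeatureConfig(families=frozenset({"F1", "F2", "F3", "F4a"}), train_lexicon=lex)
    a = _extract(fixture_doc, 4, config, prev_tags=["O", "O", "B-m", "I-m"])
    b = _extract(fixture_doc, 4, config, prev_tags=["O", "O", "B-m", "I-m"])
    assert a == b


def test_f4a_subset_of_f4b(fixture_doc):
    train = Lexicon.from_names("train", ["nitroglycerin"])
    ext = Lexicon.from_names("external", ["nitroglycerin", "sublingual spray"])
    cfg_a = FeatureConfig(families=frozenset({"F4a"}), train_lexicon=train)
    cfg_b = FeatureConfig(families=frozenset({"F4a", "F4b"}), train_lexicon=train,
                          external_lexicon=ext)
    for i in range(8):
        fa = _extract(fixture_doc, i, cfg_a)
        fb = _extract(fixture_doc, i, cfg_b)
        assert set(fa) <= set(fb)


def test_lexicon_membership_fires_on_constituent_ngram(fixture_doc):
    lex = Lexicon.from_names("train", ["Nitroglycerin"])
    config = FeatureConfig(families=frozenset({"F4a"}), train_lexicon=lex)
    feats = _extract(fixture_doc, 4, config)
    assert "F4a:train:in_1gram" in feats
    assert _extract(fixture_doc, 1, config) == {}  # "took" not in any list


def test_ngram_index_equals_bruteforce_expansion():
    entries = ["flomax ( tamsulosin )", "velcardin xr", "aprizol"]
    lex = Lexicon.from_names("train", entries)
    expected = set()
    for e in lex.entries:
        toks = e.split()
        for n in (1, 2, 3):
            for i in range(len(toks) - n + 1):
                expected.add(tuple(toks[i:i + n]))
    assert set(lex.ngram_index) == expected


def test_dose_pattern_flag_variant_only():
    doc = tokenize_document("Aprizol 25 mg, po\n")
    on = FeatureConfig(families=frozenset({"F2"}), others_variant=True)
    off = FeatureConfig(families=frozenset({"F2"}), others_variant=False)
    assert "F2:dose_pattern" in _extract(doc, 1, on)      # "25" before "mg,"
    assert "F2:dose_pattern" not in _extract(doc, 2, on)  # unit itself
    assert "F2:dose_pattern" not in _extract(doc, 1, off)


def test_name_proximity_features_require_name_spans(fixture_doc):
    config = FeatureConfig(families=frozenset({"F2"}), others_variant=True)
    name = FieldSpan(field_type="m", text="nitroglycerin", start=(1, 4), end=(1, 4))
    with_names = _extract(fixture_doc, 6, config, name_spans=[name])
    without = _extract(fixture_doc, 6, config)
    assert any(k.startswith("F2:name_") for k in with_names)
    assert not any(k.startswith("F2:name_") for k in without)
    # token inside the span is flagged as such
    inside = _extract(fixture_doc, 4, config, name_spans=[name])
    assert "F2:name_inside" in inside


# --- context features -------------------------------------------------------

def test_context_features_counts_on_list_line(excerpt_doc):
    """The published list line has 8 tokens, 3 commas, name at position 0."""
    name = FieldSpan(field_type="m", text="flomax ( tamsulosin )", start=(65, 0), end=(65, 3))
    feats = extract_context_features(excerpt_doc, name)
    assert feats["ctx:commas_raw"] == 3.0
    assert feats["ctx:line_tokens_raw"] == 8.0
    assert feats["ctx:position_raw"] == 0.0
    assert "ctx:name=flomax ( tamsulosin )" in feats


def test_context_counts_match_counting_oracle():
    from medcascade.synthetic import CorpusSpec, generate_corpus

    corpus = generate_corpus(CorpusSpec(n_documents=4, seed=9))
    checked = 0
    for sdoc in corpus:
        doc = tokenize_document(sdoc.text, sdoc.doc_id)
        for entry in sdoc.entries:
            feats = extract_context_features(doc, entry.name)
            line_no = entry.name.start[0]
            raw_line = sdoc.text.split("\n")[line_no - 1]
            assert feats["ctx:line_tokens_raw"] == float(len(raw_line.split()))
            assert feats["ctx:commas_raw"] == float(raw_line.count(","))
            checked += 1
    assert checked >= 30


def test_context_single_token_line():
    doc = tokenize_document("Aprizol\n")
    name = FieldSpan(field_type="m", text="aprizol", start=(1, 0), end=(1, 0))
    feats = extract_context_features(doc, name)
    assert feats["ctx:line_tokens_raw"] == 1.0
    assert f"ctx:w[-1]={PAD_LEFT}" in feats


# --- lexicon construction ---------------------------------------------------

def test_training_lexicon_from_gold(excerpt_doc, excerpt_entries):
    lex = build_training_lexicon([(excerpt_doc, excerpt_entries)])
    assert lex.entries == frozenset({"nitroglycerin", "flomax ( tamsulosin )"})


def test_training_lexicon_empty_gold(excerpt_doc):
    assert build_training_lexicon([(excerpt_doc, [])]).entries == frozenset()


def test_external_lexicon_normalizes_and_dedups(tmp_path):
    path = tmp_path / "drugs.txt"
    path.write_text("Aspirin\naspirin \n\nNitroglycerin\n")
    lex = load_external_lexicon(path)
    assert lex.entries == frozenset({"aspirin", "nitroglycerin"})
    for name in lex.entries:  # linear-scan membership oracle
        assert (name,) in lex.ngram_index


def test_external_lexicon_missing_file(tmp_path):
    with pytest.raises(OSError, match="no_such"):
        load_external_lexicon(tmp_path / "no_such.txt")


def test_bucket_edges():
    assert [bucket(v) for v in (0, 1, 2, 3, 5, 6, 40)] == \
        ["0", "1", "2", "3-5", "3-5", "6+", "6+"]
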