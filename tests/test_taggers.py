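"""MaxEnt training, IOB encoding/decoding, and greedy sequence decoding."""

import numpy as np
import pytest

from medcascade.docmodel import FieldSpan, tokenize_document
from medcascade.features import FeatureConfig
from medcascade.taggers import (
    ALL13,
    CONTEXT2,
    NAME3,
    OTHERS11,
    MaxEntHyperparams,
    MaxEntModel,
    TagSequence,
    decode_order,
    greedy_decode,
    repair_iob,
    spans_to_tags,
    tags_to_spans,
    train_maxent,
)


def _grid_doc(n_lines=5, per_line=8):
    text = "\n".join(" ".join(f"w{i}_{j}" for j in range(per_line)) for i in range(n_lines))
    return tokenize_document(text + "\n", doc_id="grid")


def _random_spans(rng, doc, tagset, max_spans=6):
    flat = list(doc.iter_tokens())
    types = tagset.field_types
    taken = set()
    spans = []
    for _ in range(rng.integers(0, max_spans + 1)):
        start = int(rng.integers(0, len(flat)))
        length = int(rng.integers(1, 4))
        idxs = list(range(start, min(start + length, len(flat))))
        if any(i in taken for i in idxs):
            continue
        taken.update(idxs)
        toks = [flat[i] for i in idxs]
        ftype = str(rng.choice(types))
        from medcascade.docmodel import normalize_field_text
        spans.append(FieldSpan(field_type=ftype, text=normalize_field_text(toks),
                               start=toks[0].coord, end=toks[-1].coord))
    return spans


# --- spans <-> tags ----------------------------------------------------------

def test_name_span_tags(excerpt_doc):
    span = FieldSpan(field_type="m", text="flomax ( tamsulosin )", start=(65, 0), end=(65, 3))
    tags = spans_to_tags(excerpt_doc, [span], NAME3)
    flat = list(excerpt_doc.iter_tokens())
    idx = [i for i, t in enumerate(flat) if t.line_no == 65]
    assert [tags.labels[i] for i in idx[:4]] == ["B-m", "I-m", "I-m", "I-m"]
    assert all(tags.labels[i] == "O" for i in range(len(flat)) if i not in idx[:4])


def test_no_spans_all_outside(excerpt_doc):
    tags = spans_to_tags(excerpt_doc, [], NAME3)
    assert set(tags.labels) == {"O"}


def test_overlap_raises(excerpt_doc):
    a = FieldSpan(field_type="m", text="flomax (", start=(65, 0), end=(65, 1))
    b = FieldSpan(field_type="m", text="( tamsulosin", start=(65, 1), end=(65, 2))
    with pytest.raises(ValueError, match="overlap"):
        spans_to_tags(excerpt_doc, [a, b], NAME3)


def test_spans_tags_roundtrip_on_random_span_sets():
    """tags_to_spans inverts spans_to_tags for 200 random non-overlapping
    span sets over both tagsets."""
    rng = np.random.default_rng(42)
    doc = _grid_doc()
    for trial in range(200):
        tagset = ALL13 if trial % 2 else OTHERS11
        spans = _random_spans(rng, doc, tagset)
        recovered = tags_to_spans(doc, spans_to_tags(doc, spans, tagset))
        assert sorted(recovered, key=lambda s: (s.start, s.field_type)) == \
            sorted(spans, key=lambda s: (s.start, s.field_type))


def test_orphan_inside_tag_repaired_to_begin():
    assert repair_iob(["O", "I-do", "I-do"]) == ["O", "B-do", "I-do"]
    assert repair_iob(["I-f", "I-do"]) == ["B-f", "B-do"]
    assert repair_iob(["B-m", "I-m", "O"]) == ["B-m", "I-m", "O"]
    doc = _grid_doc(1, 3)
    spans = tags_to_spans(doc, TagSequence(OTHERS11, ["O", "I-do", "I-do"]))
    assert len(spans) == 1 and spans[0].field_type == "do"
    assert (spans[0].start, spans[0].end) == ((1, 1), (1, 2))


# --- training ----------------------------------------------------------------

def test_single_label_yields_constant_model():
    model = train_maxent([({"a": 1.0}, "O")] * 5, NAME3)
    assert model.is_constant
    assert model.predict({"zzz": 1.0}) == "O"


def test_empty_instances_error():
    with pytest.raises(ValueError):
        train_maxent([], NAME3)


def test_separable_toy_set_fits_perfectly():
    """A linearly separable 20-instance set is classified perfectly on
    its own training data (verified separable by construction: disjoint
    single active features per class)."""
    instances = [({"left": 1.0, f"n{i}": 1.0}, "B-m") for i in range(10)]
    instances += [({"right": 1.0, f"n{i + 10}": 1.0}, "O") for i in range(10)]
    model = train_maxent(instances, NAME3)
    assert all(model.predict(f) == y for f, y in instances)


def test_posteriors_normalize():
    instances = [({"a": 1.0}, "B-m"), ({"b": 1.0}, "I-m"), ({"c": 1.0}, "O")] * 3
    model = train_maxent(instances, NAME3)
    for feats in ({"a": 1.0}, {"a": 1.0, "b": 2.0}, {}, {"unseen": 5.0}):
        assert abs(sum(model.predict_proba(feats).values()) - 1.0) < 1e-9


def test_stronger_l2_never_increases_training_likelihood():
    rng = np.random.default_rng(0)
    instances = []
    for i in range(40):
        label = "B-m" if i % 2 else "O"
        feats = {f"f{j}": float(rng.integers(0, 2)) for j in range(6)}
        feats["bias_" + label] = 1.0 if rng.random() < 0.8 else 0.0
        instances.append((feats, label))

    def loglik(model):
        return sum(np.log(model.predict_proba(f)[y]) for f, y in instances)

    lls = [loglik(train_maxent(instances, NAME3, MaxEntHyperparams(l2_strength=s)))
           for s in (0.1, 1.0, 10.0)]
    assert lls[0] >= lls[1] - 1e-6 and lls[1] >= lls[2] - 1e-6


def test_training_is_deterministic():
    instances = [({"a": 1.0, "b": float(i % 3)}, "B-m" if i % 2 else "O") for i in range(30)]
    m1 = train_maxent(instances, NAME3)
    m2 = train_maxent(instances, NAME3)
    assert m1.to_dict() == m2.to_dict()


def test_model_dict_roundtrip():
    instances = [({"a": 1.0}, "B-m"), ({"b": 1.0}, "O")] * 5
    model = train_maxent(instances, NAME3)
    clone = MaxEntModel.from_dict(model.to_dict())
    assert clone.predict_proba({"a": 1.0}) == pytest.approx(model.predict_proba({"a": 1.0}))


# --- decoding ----------------------------------------------------------------

def test_decode_order_puts_outside_last():
    assert decode_order(NAME3) == ("B-m", "I-m", "O")
    assert decode_order(CONTEXT2) == ("list", "narrative")


def test_tie_break_follows_label_order():
    model = MaxEntModel(labels=list(NAME3.labels), vocab={}, coef=np.zeros((3, 0)),
                        intercept=np.zeros(3), hyperparams=MaxEntHyperparams(),
                        tagset_name="name3")
    assert model.predict({}, decode_order(NAME3)) == "B-m"


def test_constant_outside_model_decodes_all_outside():
    doc = _grid_doc(2, 5)
    model = train_maxent([({"x": 1.0}, "O")] * 4, NAME3)
    tags = greedy_decode(doc, model, FeatureConfig(families=frozenset({"F1"})))
    assert set(tags.labels) == {"O"}


def test_greedy_without_history_equals_pointwise_argmax():
    """With F3 disabled, greedy decoding must coincide with classifying
    every token independently."""
    from medcascade.docmodel import pos_tag
    from medcascade.features import extract_token_features

    doc = _grid_doc(5, 8)  # 40 tokens
    config = FeatureConfig(families=frozenset({"F1", "F2"}))
    rng = np.random.default_rng(3)
    flat = list(doc.iter_tokens())
    pos = pos_tag(doc)
    instances = []
    for i in range(len(flat)):
        feats = extract_token_features(doc, flat, i, [], pos, config)
        label = str(rng.choice(["B-m", "I-m", "O"]))
        instances.append((feats, label))
    model = train_maxent(instances, NAME3)
    decoded = greedy_decode(doc, model, config, pos)
    order = decode_order(NAME3)
    pointwise = [model.predict(extract_token_features(doc, flat, i, [], pos, config), order)
                 for i in range(len(flat))]
    assert decoded.labels == repair_iob(pointwise)


def test_decoding_is_deterministic(excerpt_doc):
    config = FeatureConfig(families=frozenset({"F1", "F3"}))
    instances = [({"F1:w[0]=flomax": 1.0}, "B-m"), ({"F1:w[0]=po,": 1.0}, "O")] * 5
    model = train_maxent(instances, NAME3)
    t1 = greedy_decode(excerpt_doc, model, config)
    t2 = greedy_decode(excerpt_doc, model, config)
    assert t1.labels == t2.labels


def test_decoded_sequences_are_valid_iob(excerpt_doc):
    config = FeatureConfig(families=frozenset({"F1"}))
    rng = np.random.default_rng(1)
    instances = [({f"F1:w[0]={w}": 1.0}, str(rng.choice(list(ALL13.labels))))
                 for w in ("a", "b", "c", "d", "e", "f", "g", "h") for _ in range(3)]
    model = train_maxent(instances, ALL13)
    tags = greedy_decode(excerpt_doc, model, config)
    for i, lb in enumerate(tags.labels):
        if lb.startswith("I-"):
            assert tags.labels[i - 1] in (f"B-{lb[2:]}", f"I-{lb[2:]}")
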