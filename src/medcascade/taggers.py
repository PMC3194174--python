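"""Maximum-entropy classification and greedy IOB decoding.

Field detection is token-level sequence labeling under the IOB scheme.
The cascade runs three classifiers: ``find_name`` (3 tags: B-m, I-m, O)
detects medication names, ``context_type`` labels each detected name as
appearing in a list or in narrative text, and ``find_others`` (11 tags)
detects the five non-name field types using, among others, features that
reference the detected names.  The single-pass alternative ``find_all``
(13 tags) detects all six field types at once and therefore cannot use
features that look at a previous module's output.

The classifier is multinomial logistic regression (maximum entropy) with
an L2 penalty.  Decoding is greedy left-to-right: each token's features
may include the tags already predicted for earlier tokens (family F3);
the argmax label is taken per token, with ties broken by the tagset's
fixed label order, O last.  An IOB repair pass turns any orphan I-x into
B-x so decoded sequences always form valid spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from medcascade.docmodel import (
    NON_NAME_TYPES,
    Document,
    FieldSpan,
    normalize_field_text,
    pos_tag,
)
from medcascade.features import FeatureConfig, extract_context_features, extract_token_features


def _iob_labels(types: Sequence[str]) -> tuple[str, ...]:
    labels: list[str] = []
    for t in types:
        labels.extend((f"B-{t}", f"I-{t}"))
    labels.append("O")
    return tuple(labels)


@dataclass(frozen=True)
class Tagset:
    """A named label inventory; ``labels`` fixes the tie-break order
    (O is last so content tags win ties)."""

    name: str
    labels: tuple[str, ...]

    @property
    def field_types(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(lb[2:] for lb in self.labels if lb not in ("O",) and "-" in lb))


NAME3 = Tagset("name3", _iob_labels(("m",)))
OTHERS11 = Tagset("others11", _iob_labels(NON_NAME_TYPES))
ALL13 = Tagset("all13", _iob_labels(("m",) + NON_NAME_TYPES))
CONTEXT2 = Tagset("context2", ("list", "narrative"))

TAGSETS = {t.name: t for t in (NAME3, OTHERS11, ALL13, CONTEXT2)}


@dataclass
class TagSequence:
    """Per-token labels aligned with a document's reading-order stream."""

    tagset: Tagset
    labels: list[str]

    def __post_init__(self) -> None:
        bad = [lb for lb in self.labels if lb not in self.tagset.labels]
        if bad:
            raise ValueError(f"labels outside tagset {self.tagset.name}: {sorted(set(bad))[:5]}")


@dataclass(frozen=True)
class MaxEntHyperparams:
    """L2-penalized MaxEnt training settings."""

    l2_strength: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0


class MaxEntModel:
    """A trained maximum-entropy (multinomial logistic) classifier over
    sparse named features.

    Stores the label list, the feature vocabulary, and one weight vector
    per label; prediction works directly from feature dictionaries so a
    single token can be scored cheaply during greedy decoding.
    """

    def __init__(
        self,
        labels: Sequence[str],
        vocab: Mapping[str, int],
        coef: np.ndarray,
        intercept: np.ndarray,
        hyperparams: MaxEntHyperparams,
        tagset_name: str = "",
    ) -> None:
        self.labels = list(labels)
        self.vocab = dict(vocab)
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = np.asarray(intercept, dtype=float)
        self.hyperparams = hyperparams
        self.tagset_name = tagset_name
        if self.coef.shape != (len(self.labels), len(self.vocab)):
            raise ValueError("coefficient matrix shape does not match labels x vocabulary")
        if not np.all(np.isfinite(self.coef)) or not np.all(np.isfinite(self.intercept)):
            raise ValueError("non-finite model weights")

    @property
    def is_constant(self) -> bool:
        return len(self.labels) == 1

    def scores(self, feats: Mapping[str, float]) -> np.ndarray:
        """Unnormalized log-scores for each label."""
        z = self.intercept.copy()
        vocab = self.vocab
        coef = self.coef
        for name, value in feats.items():
            j = vocab.get(name)
            if j is not None:
                z += coef[:, j] * value
        return z

    def predict_proba(self, feats: Mapping[str, float]) -> dict[str, float]:
        z = self.scores(feats)
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        return dict(zip(self.labels, p))

    def predict(self, feats: Mapping[str, float], label_order: Sequence[str] | None = None) -> str:
        """Argmax label; ties resolved by ``label_order`` (default: the
        model's label list)."""
        z = self.scores(feats)
        order = label_order if label_order is not None else self.labels
        best_label = None
        best_score = -np.inf
        by_label = dict(zip(self.labels, z))
        for lb in order:
            s = by_label.get(lb)
            if s is not None and s > best_score:
                best_score = s
                best_label = lb
        assert best_label is not None
        return best_label

    def to_dict(self) -> dict:
        feature_names = sorted(self.vocab, key=self.vocab.get)
        return {
            "format_version": 1,
            "tagset": self.tagset_name,
            "labels": self.labels,
            "feature_names": feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "hyperparams": {
                "l2_strength": self.hyperparams.l2_strength,
                "tol": self.hyperparams.tol,
                "max_iter": self.hyperparams.max_iter,
                "seed": self.hyperparams.seed,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaxEntModel":
        if data.get("format_version") != 1:
            raise ValueError(f"unsupported model format version {data.get('format_version')!r}")
        hp = MaxEntHyperparams(**data["hyperparams"])
        vocab = {name: j for j, name in enumerate(data["feature_names"])}
        return cls(
            labels=data["labels"],
            vocab=vocab,
            coef=np.asarray(data["coef"], dtype=float),
            intercept=np.asarray(data["intercept"], dtype=float),
            hyperparams=hp,
            tagset_name=data.get("tagset", ""),
        )


def train_maxent(
    instances: Sequence[tuple[Mapping[str, float], str]],
    tagset: Tagset,
    hyperparams: MaxEntHyperparams | None = None,
) -> MaxEntModel:
    """Fit an L2-penalized multinomial logistic model on labeled feature
    dictionaries.

    With fewer than two distinct labels the result is a constant model.
    Training is deterministic given the instance order and seed.
    """
    if not instances:
        raise ValueError("cannot train on an empty instance set")
    hp = hyperparams or MaxEntHyperparams()
    feats = [dict(f) for f, _ in instances]
    y = [lb for _, lb in instances]
    unknown = set(y) - set(tagset.labels)
    if unknown:
        raise ValueError(f"labels outside tagset {tagset.name}: {sorted(unknown)}")
    if len(set(y)) < 2:
        return MaxEntModel(
            labels=[y[0]], vocab={}, coef=np.zeros((1, 0)), intercept=np.zeros(1),
            hyperparams=hp, tagset_name=tagset.name,
        )
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(feats)
    # sklearn's default penalty is the L2 norm used here
    clf = LogisticRegression(
        C=1.0 / hp.l2_strength,
        solver="lbfgs",
        tol=hp.tol,
        max_iter=hp.max_iter,
        random_state=hp.seed,
    )
    clf.fit(X, y)
    vocab = {name: j for j, name in enumerate(vectorizer.get_feature_names_out())}
    if len(clf.classes_) == 2:
        # binary sklearn fit stores one row; expand to one row per class
        coef = np.vstack([-clf.coef_[0], clf.coef_[0]])
        intercept = np.array([-clf.intercept_[0], clf.intercept_[0]])
    else:
        coef = clf.coef_
        intercept = clf.intercept_
    return MaxEntModel(
        labels=list(clf.classes_), vocab=vocab, coef=coef, intercept=intercept,
        hyperparams=hp, tagset_name=tagset.name,
    )


# ---------------------------------------------------------------------------
# Spans <-> IOB tags
# ---------------------------------------------------------------------------

def spans_to_tags(doc: Document, spans: Iterable[FieldSpan], tagset: Tagset) -> TagSequence:
    """Encode field spans as an IOB tag sequence over the document.

    Raises on overlapping spans or a span whose field type is outside the
    tagset.
    """
    flat = list(doc.iter_tokens())
    coord_to_index = {t.coord: i for i, t in enumerate(flat)}
    labels = ["O"] * len(flat)
    owner: list[FieldSpan | None] = [None] * len(flat)
    for span in spans:
        if not span.present:
            continue
        if span.field_type not in tagset.field_types:
            raise ValueError(f"field type {span.field_type!r} not in tagset {tagset.name}")
        toks = doc.tokens_in_span(span.start, span.end)
        for k, tok in enumerate(toks):
            i = coord_to_index[tok.coord]
            if owner[i] is not None:
                raise ValueError(f"overlapping spans at {tok.coord}: {owner[i]} vs {span}")
            owner[i] = span
            labels[i] = ("B-" if k == 0 else "I-") + span.field_type
    return TagSequence(tagset=tagset, labels=labels)


def repair_iob(labels: Sequence[str]) -> list[str]:
    """Turn any I-x without a preceding B-x/I-x of the same type into B-x."""
    out: list[str] = []
    for i, lb in enumerate(labels):
        if lb.startswith("I-"):
            prev = out[i - 1] if i > 0 else "O"
            if prev not in (f"B-{lb[2:]}", f"I-{lb[2:]}"):
                lb = "B-" + lb[2:]
        out.append(lb)
    return out


def tags_to_spans(doc: Document, tags: TagSequence) -> list[FieldSpan]:
    """Decode maximal B-x (I-x)* runs into field spans.

    Orphan I-x labels are repaired to B-x first, so any label sequence
    yields a valid span set.  Span text comes from normalizing the covered
    tokens.
    """
    flat = list(doc.iter_tokens())
    labels = repair_iob(tags.labels)
    spans: list[FieldSpan] = []
    run: list[int] = []
    run_type = ""

    def flush() -> None:
        if run:
            toks = [flat[i] for i in run]
            spans.append(FieldSpan(
                field_type=run_type,
                text=normalize_field_text(toks),
                start=toks[0].coord,
                end=toks[-1].coord,
            ))

    for i, lb in enumerate(labels):
        if lb.startswith("B-"):
            flush()
            run = [i]
            run_type = lb[2:]
        elif lb.startswith("I-"):
            run.append(i)
        else:
            flush()
            run = []
    flush()
    return spans


# ---------------------------------------------------------------------------
# Greedy decoding and the two architectures
# ---------------------------------------------------------------------------

def decode_order(tagset: Tagset) -> tuple[str, ...]:
    """Tie-break order: tagset label order with O last."""
    return tuple(lb for lb in tagset.labels if lb != "O") + (("O",) if "O" in tagset.labels else ())


def greedy_decode(
    doc: Document,
    model: MaxEntModel,
    config: FeatureConfig,
    pos_labels: Mapping[tuple[int, int], str] | None = None,
    name_spans: Sequence[FieldSpan] | None = None,
) -> TagSequence:
    """Left-to-right per-token decoding with previously predicted tags
    available as F3 features, followed by IOB repair."""
    tagset = TAGSETS[model.tagset_name]
    order = decode_order(tagset)
    if pos_labels is None:
        pos_labels = pos_tag(doc)
    flat = list(doc.iter_tokens())
    predicted: list[str] = []
    for i in range(len(flat)):
        feats = extract_token_features(doc, flat, i, predicted, pos_labels, config, name_spans)
        predicted.append(model.predict(feats, order))
    return TagSequence(tagset=tagset, labels=repair_iob(predicted))


def _exclusion_filter(doc: Document, spans: Sequence[FieldSpan]) -> list[FieldSpan]:
    """Drop spans that start inside an excluded section."""
    kept = []
    for span in spans:
        sec = doc.section_of(span.start[0])
        if sec is None or not sec.excluded:
            kept.append(span)
    return kept


def classify_contexts(
    doc: Document, name_spans: Sequence[FieldSpan], model: MaxEntModel
) -> list[str]:
    """list/narrative label for each detected name occurrence."""
    out = []
    for span in name_spans:
        feats = extract_context_features(doc, span)
        out.append(model.predict(feats, CONTEXT2.labels))
    return out


def run_cascade(
    doc: Document,
    find_name: MaxEntModel,
    context_type: MaxEntModel,
    find_others: MaxEntModel,
    name_config: FeatureConfig,
    others_config: FeatureConfig,
    pos_labels: Mapping[tuple[int, int], str] | None = None,
) -> tuple[list[tuple[FieldSpan, str]], list[FieldSpan]]:
    """The three-module cascade on one document.

    Returns (name spans each paired with its ln label, non-name spans),
    both after the excluded-section filter.  The non-name tagger sees the
    detected names through its proximity features.
    """
    if pos_labels is None:
        pos_labels = pos_tag(doc)
    name_tags = greedy_decode(doc, find_name, name_config, pos_labels)
    name_spans = tags_to_spans(doc, name_tags)
    others_tags = greedy_decode(doc, find_others, others_config, pos_labels,
                                name_spans=name_spans if name_spans else None)
    other_spans = tags_to_spans(doc, others_tags)
    name_spans = _exclusion_filter(doc, name_spans)
    other_spans = _exclusion_filter(doc, other_spans)
    ln_labels = classify_contexts(doc, name_spans, context_type)
    return list(zip(name_spans, ln_labels)), other_spans


def run_find_all(
    doc: Document,
    find_all: MaxEntModel,
    context_type: MaxEntModel,
    config: FeatureConfig,
    pos_labels: Mapping[tuple[int, int], str] | None = None,
) -> tuple[list[tuple[FieldSpan, str]], list[FieldSpan]]:
    """The single-pass 13-way alternative.

    One decoding pass yields all six field types; features that reference
    a previous module's output are unavailable by construction (no name
    spans are passed).  Complete entries still need ln labels, which come
    from the context classifier applied to the detected names.
    """
    if pos_labels is None:
        pos_labels = pos_tag(doc)
    tags = greedy_decode(doc, find_all, config, pos_labels)
    spans = _exclusion_filter(doc, tags_to_spans(doc, tags))
    name_spans = [s for s in spans if s.field_type == "m"]
    other_spans = [s for s in spans if s.field_type != "m"]
    ln_labels = classify_contexts(doc, name_spans, context_type)
    return list(zip(name_spans, ln_labels)), other_spans
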