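"""End-to-end orchestration: corpus I/O, training, prediction, scoring,
and the two experiment harnesses (learning curve, cascade vs. single-pass).

A trained system is a :class:`ModelBundle`: the three cascade classifiers
(optionally plus the 13-way single-pass model), the heading lexicon and
section configuration, the feature configuration, and the medication-name
lexicons needed at prediction time.  Bundles serialize to a directory of
JSON files with a manifest recording configuration, seed, and lexicon
hashes, so a run is reproducible from its bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from medcascade.docmodel import (
    Document,
    Entry,
    FieldSpan,
    SectionConfig,
    collect_headings,
    parse_entries,
    pos_tag,
    segment_sections,
    tokenize_document,
    write_entries,
)
from medcascade.evaluation import MetricReport, approx_randomization_test, full_report
from medcascade.features import FeatureConfig, Lexicon, build_training_lexicon, extract_context_features, extract_token_features
from medcascade.linker import LinkConfig, link_and_assemble
from medcascade.synthetic import SyntheticDocument
from medcascade.taggers import (
    ALL13,
    CONTEXT2,
    NAME3,
    OTHERS11,
    MaxEntHyperparams,
    MaxEntModel,
    run_cascade,
    run_find_all,
    spans_to_tags,
    train_maxent,
)

logger = logging.getLogger(__name__)

GoldCorpus = Sequence[tuple[Document, Sequence[Entry]]]


@dataclass(frozen=True)
class PipelineConfig:
    """Feature, training, sectioning, and linking settings for one run."""

    families: frozenset[str] = frozenset({"F1", "F2", "F3", "F4a"})
    ngram_window: int = 2
    affix_max_len: int = 4
    hyperparams: MaxEntHyperparams = MaxEntHyperparams()
    section_config: SectionConfig = SectionConfig()
    link_config: LinkConfig = LinkConfig()
    train_find_all: bool = False

    def feature_config(self, others_variant: bool, train_lexicon: Lexicon | None,
                       external_lexicon: Lexicon | None) -> FeatureConfig:
        return FeatureConfig(
            families=self.families,
            ngram_window=self.ngram_window,
            affix_max_len=self.affix_max_len,
            others_variant=others_variant,
            train_lexicon=train_lexicon,
            external_lexicon=external_lexicon if "F4b" in self.families else None,
        )


@dataclass
class ModelBundle:
    """Everything needed to run prediction."""

    find_name: MaxEntModel
    context_type: MaxEntModel
    find_others: MaxEntModel
    find_all: MaxEntModel | None
    headings: set[str]
    config: PipelineConfig
    train_lexicon: Lexicon
    external_lexicon: Lexicon | None
    manifest: dict

    def name_config(self) -> FeatureConfig:
        return self.config.feature_config(False, self.train_lexicon, self.external_lexicon)

    def others_config(self) -> FeatureConfig:
        return self.config.feature_config(True, self.train_lexicon, self.external_lexicon)

    # -- serialization -----------------------------------------------------

    def save(self, bundle_dir: "str | Path") -> None:
        out = Path(bundle_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "manifest": self.manifest,
            "headings": sorted(self.headings),
            "families": sorted(self.config.families),
            "ngram_window": self.config.ngram_window,
            "affix_max_len": self.config.affix_max_len,
            "section_config": {
                "heading_frequency_threshold": self.config.section_config.heading_frequency_threshold,
                "excluded_headings": sorted(self.config.section_config.excluded_headings),
            },
            "link_config": {"subsequent_override_margin": self.config.link_config.subsequent_override_margin},
            "hyperparams": self.find_name.to_dict()["hyperparams"],
            "train_lexicon": sorted(self.train_lexicon.entries),
            "external_lexicon": sorted(self.external_lexicon.entries) if self.external_lexicon else None,
            "has_find_all": self.find_all is not None,
        }
        (out / "bundle.json").write_text(json.dumps(meta, indent=1))
        for name, model in self._models().items():
            (out / f"{name}.json").write_text(json.dumps(model.to_dict()))

    def _models(self) -> dict[str, MaxEntModel]:
        models = {"find_name": self.find_name, "context_type": self.context_type,
                  "find_others": self.find_others}
        if self.find_all is not None:
            models["find_all"] = self.find_all
        return models

    @classmethod
    def load(cls, bundle_dir: "str | Path") -> "ModelBundle":
        src = Path(bundle_dir)
        meta = json.loads((src / "bundle.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported bundle format {meta.get('format_version')!r}")
        hp = MaxEntHyperparams(**meta["hyperparams"])
        config = PipelineConfig(
            families=frozenset(meta["families"]),
            ngram_window=meta["ngram_window"],
            affix_max_len=meta["affix_max_len"],
            hyperparams=hp,
            section_config=SectionConfig(
                heading_frequency_threshold=meta["section_config"]["heading_frequency_threshold"],
                excluded_headings=frozenset(meta["section_config"]["excluded_headings"]),
            ),
            link_config=LinkConfig(**meta["link_config"]),
            train_find_all=meta["has_find_all"],
        )
        models = {}
        for name in ("find_name", "context_type", "find_others", "find_all"):
            path = src / f"{name}.json"
            models[name] = MaxEntModel.from_dict(json.loads(path.read_text())) if path.exists() else None
        return cls(
            find_name=models["find_name"],
            context_type=models["context_type"],
            find_others=models["find_others"],
            find_all=models["find_all"],
            headings=set(meta["headings"]),
            config=config,
            train_lexicon=Lexicon(name="train", entries=frozenset(meta["train_lexicon"])),
            external_lexicon=(Lexicon(name="external", entries=frozenset(meta["external_lexicon"]))
                              if meta["external_lexicon"] is not None else None),
            manifest=meta["manifest"],
        )


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------

def read_corpus_dir(corpus_dir: "str | Path", gold_dir: "str | Path | None" = None,
                    require_gold: bool = True) -> list[tuple[Document, list[Entry] | None]]:
    """Read one tokenized document per .txt file, with .ann gold entries
    from ``gold_dir`` when given."""
    corpus_dir = Path(corpus_dir)
    out: list[tuple[Document, list[Entry] | None]] = []
    txt_files = sorted(corpus_dir.glob("*.txt"))
    if not txt_files:
        raise FileNotFoundError(f"no .txt documents in {corpus_dir}")
    for txt in txt_files:
        doc = tokenize_document(txt.read_text(), doc_id=txt.stem)
        entries: list[Entry] | None = None
        if gold_dir is not None:
            ann = Path(gold_dir) / f"{txt.stem}.ann"
            if ann.exists():
                entries = parse_entries(ann.read_text())
            elif require_gold:
                raise FileNotFoundError(f"missing gold annotation for document {txt.stem}: {ann}")
        out.append((doc, entries))
    return out


def corpus_from_synthetic(docs: Sequence[SyntheticDocument]) -> list[tuple[Document, list[Entry]]]:
    return [(tokenize_document(d.text, d.doc_id), list(d.entries)) for d in docs]


def _dedup_spans(spans: Iterable[FieldSpan]) -> list[FieldSpan]:
    seen = {}
    for s in spans:
        seen.setdefault((s.field_type, s.start, s.end), s)
    return sorted(seen.values(), key=lambda s: (s.start, s.end, s.field_type))


def gold_spans(entries: Sequence[Entry]) -> tuple[list[FieldSpan], list[FieldSpan]]:
    """Deduplicated (name spans, non-name spans) of a gold entry list."""
    names = _dedup_spans(e.name for e in entries)
    others = _dedup_spans(s for e in entries for s in e.present_fields() if s.field_type != "m")
    return names, others


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _reconstructed_lines(doc: Document) -> list[str]:
    return [" ".join(t.text for t in line) for line in doc.lines]


def _tagging_instances(doc: Document, pos_labels, spans, tagset, config: FeatureConfig,
                       name_spans=None) -> list[tuple[dict, str]]:
    """Token-level training instances with gold previous tags (teacher
    forcing) for the F3 features."""
    flat = list(doc.iter_tokens())
    tags = spans_to_tags(doc, spans, tagset).labels
    out = []
    for i in range(len(flat)):
        feats = extract_token_features(doc, flat, i, tags[:i], pos_labels, config, name_spans)
        out.append((feats, tags[i]))
    return out


def train_pipeline(gold: GoldCorpus, config: PipelineConfig | None = None,
                   external_lexicon: Lexicon | None = None) -> ModelBundle:
    """Train the cascade (and optionally the single-pass model) on a gold
    corpus of (tokenized document, entries) pairs."""
    if not gold:
        raise ValueError("training corpus is empty")
    config = config or PipelineConfig()
    train_lexicon = build_training_lexicon(gold)
    if "F4b" in config.families and external_lexicon is None:
        raise ValueError("feature family F4b requires an external lexicon")
    headings = collect_headings(
        ("\n".join(_reconstructed_lines(doc)) for doc, _ in gold), config.section_config)

    name_cfg = config.feature_config(False, train_lexicon, external_lexicon)
    others_cfg = config.feature_config(True, train_lexicon, external_lexicon)

    name_instances: list[tuple[dict, str]] = []
    ctx_instances: list[tuple[dict, str]] = []
    others_instances: list[tuple[dict, str]] = []
    all_instances: list[tuple[dict, str]] = []
    for doc, entries in gold:
        segment_sections(doc, headings, config.section_config)
        pos_labels = pos_tag(doc)
        names, others = gold_spans(entries)
        name_instances.extend(_tagging_instances(doc, pos_labels, names, NAME3, name_cfg))
        others_instances.extend(
            _tagging_instances(doc, pos_labels, others, OTHERS11, others_cfg,
                               name_spans=names or None))
        seen_ctx = set()
        for entry in entries:
            key = (entry.name.start, entry.name.end)
            if key in seen_ctx:
                continue
            seen_ctx.add(key)
            ctx_instances.append((extract_context_features(doc, entry.name), entry.ln))
        if config.train_find_all:
            all_instances.extend(
                _tagging_instances(doc, pos_labels, names + others, ALL13, others_cfg))

    logger.info("training on %d documents: %d token instances (name), %d (others), %d contexts",
                len(gold), len(name_instances), len(others_instances), len(ctx_instances))
    hp = config.hyperparams
    bundle = ModelBundle(
        find_name=train_maxent(name_instances, NAME3, hp),
        context_type=train_maxent(ctx_instances, CONTEXT2, hp),
        find_others=train_maxent(others_instances, OTHERS11, hp),
        find_all=train_maxent(all_instances, ALL13, hp) if config.train_find_all else None,
        headings=headings,
        config=config,
        train_lexicon=train_lexicon,
        external_lexicon=external_lexicon if "F4b" in config.families else None,
        manifest={
            "n_documents": len(gold),
            "families": sorted(config.families),
            "seed": hp.seed,
            "train_lexicon_sha256": _lexicon_hash(train_lexicon),
            "external_lexicon_sha256": _lexicon_hash(external_lexicon) if external_lexicon else None,
            "n_headings": len(headings),
        },
    )
    return bundle


def _lexicon_hash(lex: Lexicon) -> str:
    return hashlib.sha256("\n".join(sorted(lex.entries)).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict_document(doc: Document, bundle: ModelBundle, mode: str = "cascade") -> list[Entry]:
    """Pre-process, detect fields, filter excluded sections, and link."""
    segment_sections(doc, bundle.headings, bundle.config.section_config)
    pos_labels = pos_tag(doc)
    if mode == "cascade":
        names_ln, others = run_cascade(
            doc, bundle.find_name, bundle.context_type, bundle.find_others,
            bundle.name_config(), bundle.others_config(), pos_labels)
    elif mode == "find_all":
        if bundle.find_all is None:
            raise ValueError("bundle has no find_all model")
        names_ln, others = run_find_all(
            doc, bundle.find_all, bundle.context_type, bundle.others_config(), pos_labels)
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return link_and_assemble(names_ln, others, bundle.config.link_config)


def predict_corpus(docs: Sequence[Document], bundle: ModelBundle,
                   mode: str = "cascade") -> dict[str, list[Entry]]:
    return {doc.doc_id: predict_document(doc, bundle, mode) for doc in docs}


def evaluate_corpus(system: Mapping[str, Sequence[Entry]],
                    gold: Mapping[str, Sequence[Entry]],
                    with_context_accuracy: bool = False) -> MetricReport:
    return full_report(system, gold, with_context_accuracy=with_context_accuracy)


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------

def split_corpus(gold: GoldCorpus, eval_fraction: float, seed: int
                 ) -> tuple[list, list]:
    """Document-level split: seeded shuffle, then first documents form the
    training pool and the tail the held-out evaluation set."""
    order = list(range(len(gold)))
    np.random.default_rng(seed).shuffle(order)
    n_eval = max(1, int(round(eval_fraction * len(gold))))
    train_idx, eval_idx = order[:-n_eval], order[-n_eval:]
    return [gold[i] for i in train_idx], [gold[i] for i in eval_idx]


def _gold_mapping(gold: GoldCorpus) -> dict[str, list[Entry]]:
    return {doc.doc_id: list(entries) for doc, entries in gold}


def learning_curve(
    gold: GoldCorpus,
    fractions: Sequence[float],
    seed: int = 0,
    base_config: PipelineConfig | None = None,
    external_lexicon: Lexicon | None = None,
    variants: Sequence[str] = ("F1-F4a", "F1-F4b"),
    eval_fraction: float = 0.3,
) -> list[dict]:
    """Train on growing portions of the training pool with and without
    the external drug list; report held-out horizontal F per cell."""
    base_config = base_config or PipelineConfig()
    train_pool, eval_set = split_corpus(gold, eval_fraction, seed)
    eval_docs = [doc for doc, _ in eval_set]
    gold_map = _gold_mapping(eval_set)
    family_sets = {
        "F1": frozenset({"F1"}),
        "F1-F2": frozenset({"F1", "F2"}),
        "F1-F3": frozenset({"F1", "F2", "F3"}),
        "F1-F4a": frozenset({"F1", "F2", "F3", "F4a"}),
        "F1-F4b": frozenset({"F1", "F2", "F3", "F4a", "F4b"}),
    }
    rows = []
    for fraction in fractions:
        n_train = int(round(fraction * len(train_pool)))
        if n_train < 1:
            logger.warning("fraction %.3f yields no training documents; skipped", fraction)
            continue
        subset = train_pool[:n_train]
        for variant in variants:
            config = replace(base_config, families=family_sets[variant])
            bundle = train_pipeline(
                subset, config,
                external_lexicon=external_lexicon if "F4b" in family_sets[variant] else None)
            system = predict_corpus(eval_docs, bundle)
            report = evaluate_corpus(system, gold_map)
            rows.append({
                "fraction": fraction,
                "n_train": n_train,
                "variant": variant,
                "horizontal_f": report.horizontal.f,
                "horizontal_precision": report.horizontal.precision,
                "horizontal_recall": report.horizontal.recall,
            })
    return rows


def cascade_vs_findall(
    gold: GoldCorpus,
    fractions: Sequence[float],
    seed: int = 0,
    base_config: PipelineConfig | None = None,
    external_lexicon: Lexicon | None = None,
    eval_fraction: float = 0.3,
    n_shuffles: int = 10_000,
) -> list[dict]:
    """Paired comparison of the cascade against the single-pass 13-way
    tagger per training fraction, with approximate-randomization p."""
    base_config = replace(base_config or PipelineConfig(), train_find_all=True)
    train_pool, eval_set = split_corpus(gold, eval_fraction, seed)
    eval_docs = [doc for doc, _ in eval_set]
    gold_map = _gold_mapping(eval_set)
    rows = []
    for fraction in fractions:
        n_train = int(round(fraction * len(train_pool)))
        if n_train < 1:
            logger.warning("fraction %.3f yields no training documents; skipped", fraction)
            continue
        bundle = train_pipeline(train_pool[:n_train], base_config, external_lexicon)
        out_cascade = predict_corpus(eval_docs, bundle, mode="cascade")
        out_findall = predict_corpus(eval_docs, bundle, mode="find_all")
        f_cascade = evaluate_corpus(out_cascade, gold_map).horizontal.f
        f_findall = evaluate_corpus(out_findall, gold_map).horizontal.f
        test = approx_randomization_test(out_cascade, out_findall, gold_map,
                                         n=n_shuffles, seed=seed)
        rows.append({
            "fraction": fraction,
            "n_train": n_train,
            "cascade_f": f_cascade,
            "find_all_f": f_findall,
            "p_value": test.p,
            "observed_diff": test.observed_diff,
        })
    return rows
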