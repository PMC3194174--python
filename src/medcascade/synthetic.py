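"""Seeded generator of annotated synthetic discharge summaries.

The generator emulates the structure of real discharge summaries — headed
sections, a medication list with lines like ``Aprizol 25 mg, po, bid,``,
and narrative sections whose sentences mention medications with modes and
reasons — together with gold entries in the annotation format, so the
whole extraction pipeline can be trained and evaluated without access to
restricted clinical data.  All vocabulary is invented and non-clinical.

Per-entry field presence probabilities default to the per-name ratios
observed in the reference data (about 0.52 dosages, 0.47 frequencies,
0.39 modes, 0.06 durations, and 0.16 reasons per name), and per-document
entry density defaults to a quarter of the long-note reference (~34
names per document) to keep generated corpora small.  Duration and
reason phrases are deliberately longer and more lexically variable than
the closed-class dosage/mode/frequency fields, reproducing the
well-known difficulty ordering among the six field types.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from medcascade.docmodel import (
    Entry,
    FieldSpan,
    normalize_field_text,
    write_entries,
)

# ---------------------------------------------------------------------------
# Fixture vocabularies (synthetic, non-clinical)
# ---------------------------------------------------------------------------

def _compose_drug_names() -> tuple[str, ...]:
    """A fixed list of ~300 invented brand-style names.

    The vocabulary is deliberately much larger than what a handful of
    documents can cover, so that — as with real prescribing vocabularies —
    small training sets leave many names unseen and an external drug list
    has something to contribute.
    """
    onsets = ("Apri", "Velcar", "Tobra", "Morva", "Quenta", "Zolpi", "Carbi",
              "Fexola", "Gabri", "Hydra", "Ibexo", "Janto", "Ketra", "Lomi",
              "Metra", "Nortri", "Oxapri", "Penta")
    codas = ("zol", "dine", "mab", "pril", "statin", "vex", "caine", "zide",
             "prene", "tropin", "xam", "trine", "folam", "rucil", "mizole", "lexin")
    singles = tuple(f"{a}{b}" for a in onsets for b in codas)[:280]
    suffixed = tuple(f"{base} {suf}" for base, suf in zip(
        ("Mavilor", "Nexotril", "Ocrevin", "Pazopral", "Quizarin", "Ribovex",
         "Soltrima", "Tecfidal", "Uproleve", "Vyxeosin", "Welchorin", "Xpovirex"),
        ("XR", "SR", "CR", "XR", "SR", "CR", "XR", "SR", "CR", "XR", "SR", "CR"),
    ))
    aliases = ("Flomarin ( Tasperol )", "Zentrix ( Oblimeran )",
               "Cardivol ( Mexiprene )", "Lunestra ( Dormivex )")
    return singles + suffixed + aliases


DEFAULT_DRUG_LEXICON: tuple[str, ...] = _compose_drug_names()

_DOSE_AMOUNTS = ("0.4", "2.5", "5", "10", "20", "25", "40", "50", "75", "81",
                 "100", "150", "200", "250", "325", "400", "500", "650", "800", "1000")
_DOSE_UNITS = ("mg", "mcg", "g", "ml", "units")
_MODES_LIST = ("po", "iv", "im", "sc", "pr", "sl", "topical", "inhaled")
_MODES_NARR = ("sublingual", "oral", "intravenous", "topical", "inhaled", "subcutaneous")
_FREQS = ("qd", "bid", "tid", "qid", "prn", "q4h", "q6h", "q8h", "qhs", "qam")
_FREQS_NARR = ("once daily", "twice a day", "three times daily", "every morning",
               "as needed", "at bedtime", "every six hours")
def _compose_durations() -> tuple[str, ...]:
    """Duration phrases are built compositionally so their content and
    length vary far more than the closed-class fields, as they do in real
    notes."""
    nums = ("2", "3", "5", "7", "10", "14", "21", "30", "two", "three",
            "five", "seven", "ten", "several")
    units = ("days", "weeks", "months")
    out = [f"for {n} {u}" for n in nums for u in units]
    out += [f"for the next {n} {u}" for n in nums[:8] for u in units]
    out += [f"for a total of {n} {u}" for n in nums[:6] for u in units]
    out += [f"for another {n} {u}" for n in nums[:6] for u in units]
    out += [f"x {n} days" for n in ("3", "5", "7", "10", "14")]
    out += ["for 48 hours", "for 72 hours", "until follow up",
            "until symptoms resolve", "through the end of the month",
            "until the wound heals", "until seen in clinic"]
    return tuple(out)


_DURATION_PHRASES = _compose_durations()
_REASON_ADJ = ("mild", "severe", "chronic", "recurrent", "intermittent", "vague",
               "persistent", "acute", "worsening", "occasional", "refractory",
               "longstanding", "new onset", "bothersome", "nocturnal")
_REASON_NOUN = (
    "chest discomfort", "headache", "nausea", "hypertension", "back pain",
    "insomnia", "anxiety", "fever", "cough", "joint stiffness", "leg swelling",
    "heartburn", "dizziness", "shortness of breath", "abdominal cramping",
    "muscle spasm", "itching", "constipation", "fatigue", "palpitations",
    "wheezing", "tremor", "neck stiffness", "ear pain", "eye irritation",
    "mouth sores", "hip discomfort", "knee swelling", "rib tenderness",
    "shoulder ache", "sinus congestion", "throat irritation", "toe numbness",
    "wrist pain", "ankle instability", "bladder spasm", "calf cramping",
    "facial flushing", "gait imbalance", "hand stiffness",
)
_FILLER = (
    "the patient remained stable overnight and was monitored closely",
    "vital signs were within normal limits throughout the stay",
    "he was seen by the consulting service in the morning",
    "she tolerated the procedure well without complication",
    "laboratory values trended toward normal before discharge",
    "the family was updated at the bedside regarding the plan",
    "he was encouraged to ambulate with assistance twice daily",
    "a follow up appointment was arranged with the primary provider",
    "she reported feeling much improved by hospital day three",
    "diet was advanced as tolerated without any difficulty",
)
# non-medication sentences that imitate the surface form of duration and
# reason fields; discharge notes are full of temporal and complaint phrases
# that belong to no medication event, and telling those apart is part of
# the extraction problem
_FILLER_DISTRACTOR_HEADS = (
    "he was admitted", "she presented to the clinic", "he stayed in the unit",
    "she had been symptomatic", "he remained on telemetry",
    "symptoms had been present", "she was observed",
)
# capitalized proper nouns that are not medications, so that capitalization
# alone cannot identify drug names (as in real notes, which are full of
# clinician, hospital, and service names)
_SURNAMES = ("Harwell", "Trennick", "Osgood", "Melvane", "Corbett", "Ashfield",
             "Dunmore", "Pellerin", "Stanwick", "Farrow", "Quimby", "Ravenel",
             "Holloway", "Birchall", "Mercer", "Langley", "Tolliver",
             "Wainright", "Ellsworth", "Padgett")
_SERVICES = ("Cardiology", "Neurology", "Nephrology", "Pulmonology",
             "Psychiatry", "Orthopedics")
_PLACES = ("Mercy General Hospital", "Lakeside Clinic",
           "Saint Aldric Medical Center", "Northfield Rehabilitation Facility",
           "Westbrook Imaging Center")
_NARRATIVE_HEADINGS = ("HISTORY OF PRESENT ILLNESS", "HOSPITAL COURSE")
_EXCLUDED_HEADINGS = ("FAMILY HISTORY", "ALLERGIES")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    ``mean_entries_per_doc`` is the Poisson mean of medication entries per
    document (at least one is always generated).  ``list_proportion`` is
    the probability that an entry appears in the medication list rather
    than in narrative text.  ``presence`` maps each non-name field type to
    its per-entry presence probability.  ``typo_rate`` perturbs narrative
    filler tokens only; ``distractor_rate`` inserts capitalized non-section
    lines; ``excluded_mention_rate`` plants drug mentions inside FAMILY
    HISTORY / ALLERGIES sections, which are *not* part of the gold.
    """

    n_documents: int = 100
    seed: int = 0
    drug_lexicon: tuple[str, ...] = DEFAULT_DRUG_LEXICON
    mean_entries_per_doc: float = 8.5
    list_proportion: float = 0.7
    presence: dict[str, float] = dc_field(default_factory=lambda: {
        "do": 0.52, "mo": 0.39, "f": 0.47, "du": 0.06, "r": 0.16,
    })
    typo_rate: float = 0.01
    distractor_rate: float = 0.05
    excluded_mention_rate: float = 0.25

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        if not self.drug_lexicon:
            raise ValueError("drug lexicon must be non-empty")
        for key, p in {**self.presence, "list": self.list_proportion,
                       "typo": self.typo_rate}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {key} out of [0, 1]: {p}")


@dataclass
class SyntheticDocument:
    """One generated note with its gold entries."""

    doc_id: str
    text: str
    entries: list[Entry]

    @property
    def annotation_text(self) -> str:
        return write_entries(self.entries)


# ---------------------------------------------------------------------------
# Layout machinery: tokens are planned with field roles, then laid out on
# lines, and gold spans read off the resulting coordinates.
# ---------------------------------------------------------------------------

@dataclass
class _Planned:
    """A token awaiting layout; (entry_key, field_type) marks gold fields."""

    text: str
    entry_key: int | None = None
    field_type: str | None = None


class _DocBuilder:
    def __init__(self) -> None:
        self.lines: list[list[str]] = []
        self.placed: dict[tuple[int, str], list[tuple[str, tuple[int, int]]]] = {}

    def new_line(self) -> None:
        self.lines.append([])

    def add(self, planned: Sequence[_Planned]) -> None:
        """Append tokens to the current line."""
        if not self.lines:
            self.new_line()
        line = self.lines[-1]
        line_no = len(self.lines)
        for p in planned:
            coord = (line_no, len(line))
            line.append(p.text)
            if p.entry_key is not None and p.field_type is not None:
                self.placed.setdefault((p.entry_key, p.field_type), []).append((p.text, coord))

    def add_wrapped(self, planned: Sequence[_Planned], width: int) -> None:
        """Append tokens, wrapping to a new line whenever the current line
        reaches ``width`` tokens (fields may straddle the wrap)."""
        if not self.lines:
            self.new_line()
        for p in planned:
            if len(self.lines[-1]) >= width:
                self.new_line()
            self.add([p])

    def span_for(self, entry_key: int, field_type: str) -> FieldSpan | None:
        toks = self.placed.get((entry_key, field_type))
        if not toks:
            return None
        return FieldSpan(
            field_type=field_type,
            text=normalize_field_text(t for t, _ in toks),
            start=toks[0][1],
            end=toks[-1][1],
        )

    @property
    def text(self) -> str:
        return "\n".join(" ".join(line) for line in self.lines) + "\n"


def _typo(rng: np.random.Generator, word: str) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 2))
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def _reason_phrase(rng: np.random.Generator) -> list[str]:
    noun = str(rng.choice(_REASON_NOUN)).split()
    if rng.random() < 0.6:
        return [str(rng.choice(_REASON_ADJ))] + noun
    return noun


def _sample_presence(rng: np.random.Generator, spec: CorpusSpec) -> dict[str, bool]:
    return {t: bool(rng.random() < p) for t, p in spec.presence.items()}


def _mark(tokens: Sequence[str], key: int, ftype: str | None) -> list[_Planned]:
    return [_Planned(t, key if ftype else None, ftype) for t in tokens]


def _with_comma(planned: list[_Planned]) -> list[_Planned]:
    if planned:
        last = planned[-1]
        planned[-1] = _Planned(last.text + ",", last.entry_key, last.field_type)
    return planned


def _list_line(rng: np.random.Generator, spec: CorpusSpec, key: int,
               present: dict[str, bool]) -> list[_Planned]:
    name = str(rng.choice(spec.drug_lexicon))
    out = _mark(name.split(), key, "m")
    if present["do"]:
        dose = [str(rng.choice(_DOSE_AMOUNTS)), str(rng.choice(_DOSE_UNITS))]
        out += _with_comma(_mark(dose, key, "do"))
    if present["mo"]:
        out += _with_comma(_mark([str(rng.choice(_MODES_LIST))], key, "mo"))
    if present["f"]:
        out += _with_comma(_mark([str(rng.choice(_FREQS))], key, "f"))
    if present["du"]:
        out += _with_comma(_mark(str(rng.choice(_DURATION_PHRASES)).split(), key, "du"))
    if present["r"]:
        out += _with_comma([_Planned("for")] + _mark(_reason_phrase(rng), key, "r"))
    return out


def _narrative_sentence(rng: np.random.Generator, spec: CorpusSpec, key: int,
                        present: dict[str, bool]) -> list[_Planned]:
    name = str(rng.choice(spec.drug_lexicon))
    subj = str(rng.choice(np.array(["He", "She", "The patient"], dtype=object))).split()
    verb = str(rng.choice(np.array(
        ["was started on", "took a dose of", "continued taking", "was given",
         "had been maintained on"], dtype=object))).split()
    out: list[_Planned] = []
    # reasons often precede the name in narrative ("because of X he took Y")
    if present["r"] and rng.random() < 0.45:
        lead = str(rng.choice(np.array(["Because of", "Due to", "For"], dtype=object))).split()
        out += [_Planned(t) for t in lead] + _mark(_reason_phrase(rng), key, "r")
        present = {**present, "r": False}
    out += [_Planned(t) for t in subj] + [_Planned(t) for t in verb]
    if present["mo"] and rng.random() < 0.5:
        out += _mark([str(rng.choice(_MODES_NARR))], key, "mo")
        present = {**present, "mo": False}
    out += _mark(name.split(), key, "m")
    if present["do"]:
        out += _mark([str(rng.choice(_DOSE_AMOUNTS)), str(rng.choice(_DOSE_UNITS))], key, "do")
    if present["mo"]:
        out += _mark([str(rng.choice(_MODES_NARR))], key, "mo")
    if present["f"]:
        out += _mark(str(rng.choice(_FREQS_NARR)).split(), key, "f")
    if present["du"]:
        out += _mark(str(rng.choice(_DURATION_PHRASES)).split(), key, "du")
    if present["r"]:
        out += [_Planned("for")] + _mark(_reason_phrase(rng), key, "r")
    out.append(_Planned("."))
    return out


def _proper_noun_sentence(rng: np.random.Generator) -> list[str]:
    kind = rng.random()
    if kind < 0.4:
        return f"the patient was evaluated by Dr {rng.choice(_SURNAMES)} in the morning".split()
    if kind < 0.6:
        return f"records were requested from {rng.choice(_PLACES)}".split()
    if kind < 0.8:
        return f"the case was discussed with the {rng.choice(_SERVICES)} service".split()
    return f"Dr {rng.choice(_SURNAMES)} recommended continued observation".split()


def _filler_sentence(rng: np.random.Generator, spec: CorpusSpec) -> list[_Planned]:
    roll = rng.random()
    if roll < 0.35:
        words = str(rng.choice(_FILLER_DISTRACTOR_HEADS)).split()
        if rng.random() < 0.5:
            words += str(rng.choice(_DURATION_PHRASES)).split()
        else:
            words += ["for"] + _reason_phrase(rng)
    elif roll < 0.65:
        words = _proper_noun_sentence(rng)
    else:
        words = str(rng.choice(_FILLER)).split()
    out = []
    for w in words:
        if rng.random() < spec.typo_rate:
            w = _typo(rng, w)
        out.append(_Planned(w))
    out.append(_Planned("."))
    return out


def _generate_document(rng: np.random.Generator, spec: CorpusSpec, doc_id: str) -> SyntheticDocument:
    n_entries = max(1, int(rng.poisson(spec.mean_entries_per_doc)))
    contexts = ["list" if rng.random() < spec.list_proportion else "narrative"
                for _ in range(n_entries)]
    n_narr = contexts.count("narrative")
    n_list = contexts.count("list")

    b = _DocBuilder()
    entry_meta: list[tuple[int, str, dict[str, bool]]] = []
    key = 0

    b.new_line()
    b.add([_Planned("ADMIT"), _Planned("DIAGNOSIS:")])
    b.new_line()
    b.add(_filler_sentence(rng, spec))

    # narrative sections with embedded medication sentences
    narr_keys = []
    for heading in _NARRATIVE_HEADINGS:
        quota = n_narr // 2 + (n_narr % 2 if heading == _NARRATIVE_HEADINGS[0] else 0)
        b.new_line()
        b.add([_Planned(w) for w in (heading + ":").split()])
        width = int(rng.integers(9, 14))
        sentences: list[list[_Planned]] = []
        for _ in range(quota):
            present = _sample_presence(rng, spec)
            sentences.append(_narrative_sentence(rng, spec, key, present))
            entry_meta.append((key, "narrative", present))
            narr_keys.append(key)
            key += 1
        n_filler = int(rng.integers(1, 4))
        for _ in range(n_filler):
            sentences.insert(int(rng.integers(0, len(sentences) + 1)),
                             _filler_sentence(rng, spec))
        b.new_line()
        for sent in sentences:
            b.add_wrapped(sent, width)
        if rng.random() < spec.distractor_rate:
            b.new_line()
            b.add([_Planned(w) for w in "PLAN DISCUSSED WITH THE TEAM".split()])

    # occasionally an excluded section with a drug mention kept out of gold
    if rng.random() < spec.excluded_mention_rate:
        heading = str(rng.choice(np.array(_EXCLUDED_HEADINGS, dtype=object)))
        b.new_line()
        b.add([_Planned(w) for w in (heading + ":").split()])
        b.new_line()
        drug = str(rng.choice(spec.drug_lexicon))
        if heading == "ALLERGIES":
            b.add([_Planned(t) for t in drug.split()] + [_Planned(w) for w in "causes a rash .".split()])
        else:
            b.add([_Planned(w) for w in "mother took".split()]
                  + [_Planned(t) for t in drug.split()]
                  + [_Planned(w) for w in "for hypertension .".split()])

    # the medication list
    b.new_line()
    b.add([_Planned("DISCHARGE"), _Planned("MEDICATIONS:")])
    for _ in range(n_list):
        present = _sample_presence(rng, spec)
        b.new_line()
        b.add(_list_line(rng, spec, key, present))
        entry_meta.append((key, "list", present))
        key += 1

    entries: list[Entry] = []
    for ekey, ln, _present in sorted(entry_meta, key=lambda m: m[0]):
        name = b.span_for(ekey, "m")
        assert name is not None
        slots = {}
        for t in ("do", "mo", "f", "du", "r"):
            span = b.span_for(ekey, t)
            if span is not None:
                slots[t] = span
        entries.append(Entry.build(name, ln, **slots))
    entries.sort(key=lambda e: e.name.start)
    return SyntheticDocument(doc_id=doc_id, text=b.text, entries=entries)


def generate_corpus(spec: CorpusSpec) -> list[SyntheticDocument]:
    """Generate a deterministic corpus of annotated synthetic notes."""
    rng = np.random.default_rng(spec.seed)
    return [
        _generate_document(rng, spec, f"doc{idx:04d}")
        for idx in range(spec.n_documents)
    ]


def write_corpus(corpus: Sequence[SyntheticDocument], out_dir: "str | Path") -> None:
    """Write one .txt and one .ann file per document."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in corpus:
        (out / f"{doc.doc_id}.txt").write_text(doc.text)
        (out / f"{doc.doc_id}.ann").write_text(doc.annotation_text)


def corpus_statistics(corpus: Sequence[SyntheticDocument]) -> dict[str, dict[str, float]]:
    """Totals and per-document means for entries and each field type."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    n_docs = len(corpus)
    counts = {"entries": 0, "fields": 0, "m": 0, "do": 0, "mo": 0, "f": 0, "du": 0, "r": 0}
    for doc in corpus:
        counts["entries"] += len(doc.entries)
        for entry in doc.entries:
            for span in entry.present_fields():
                counts["fields"] += 1
                counts[span.field_type] += 1
    return {
        key: {"total": float(total), "per_document": total / n_docs}
        for key, total in counts.items()
    }
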