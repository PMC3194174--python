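"""Sparse feature extraction for the token-level IOB taggers and the
list/narrative context classifier.

Feature families
----------------
F1   word n-grams (n = 1, 2, 3) over a small window around the token
F2   token-property features: POS of the token and neighbors, affixes,
     length, capitalization, digit shape, containing section heading, and
     (non-name variant) a dosage-pattern flag
F3   the previously predicted IOB tags (one and two back)
F4   gazetteer features: whether an n-gram containing the token occurs in
     a medication-name lexicon; F4a uses the lexicon built from training
     gold, F4b adds an external drug list

Feature names carry their family as a prefix so that disabling a family
removes exactly that family's features.  Numeric quantities (counts,
positions, distances) are emitted both raw and bucketed so a purely
binary learner remains usable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from medcascade.docmodel import Document, FieldSpan, Token, normalize_field_text

FAMILIES = ("F1", "F2", "F3", "F4a", "F4b")

#: padding symbols for context windows at document edges
PAD_LEFT = "<S>"
PAD_RIGHT = "</S>"

_DOSE_UNITS = {"mg", "mcg", "g", "ml", "units"}
_NUM_RE = re.compile(r"^\d+(\.\d+)?$")
_NUM_UNIT_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|units)$", re.IGNORECASE)


def bucket(value: int) -> str:
    """Coarse magnitude bucket: 0, 1, 2, 3-5, 6+."""
    if value <= 2:
        return str(value)
    if value <= 5:
        return "3-5"
    return "6+"


@dataclass(frozen=True)
class Lexicon:
    """A normalized medication-name list with an index of all constituent
    token n-grams (n = 1..3) for fast gazetteer lookups."""

    name: str
    entries: frozenset[str]
    ngram_index: frozenset[tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ngram_index is None:
            object.__setattr__(self, "ngram_index", self._build_index(self.entries))

    @staticmethod
    def _build_index(entries: Iterable[str]) -> frozenset[tuple[str, ...]]:
        index: set[tuple[str, ...]] = set()
        for entry in entries:
            toks = tuple(entry.split())
            for n in range(1, 4):
                for i in range(len(toks) - n + 1):
                    index.add(toks[i:i + n])
        return frozenset(index)

    @classmethod
    def from_names(cls, name: str, names: Iterable[str]) -> "Lexicon":
        normalized = {normalize_field_text(n.split()) for n in names if n.strip()}
        return cls(name=name, entries=frozenset(normalized))

    def has_ngram(self, ngram: tuple[str, ...]) -> bool:
        return ngram in self.ngram_index


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families are active and their shape parameters.

    ``others_variant`` switches on the features specific to non-name field
    detection (the dosage-pattern flag); name-proximity features require
    detected name spans and are controlled by passing ``name_spans``.
    Enabling F4b implies the F4a training lexicon is also consulted.
    """

    families: frozenset[str] = frozenset({"F1", "F2", "F3", "F4a"})
    ngram_window: int = 2
    affix_max_len: int = 4
    others_variant: bool = False
    train_lexicon: Lexicon | None = None
    external_lexicon: Lexicon | None = None

    def __post_init__(self) -> None:
        unknown = self.families - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.ngram_window < 1:
            raise ValueError("ngram_window must be >= 1")
        if "F4b" in self.families and self.external_lexicon is None:
            raise ValueError("F4b enabled without an external lexicon")

    def active_lexicons(self) -> list[tuple[str, Lexicon]]:
        """(family prefix, lexicon) pairs in effect.  F4b implies F4a."""
        out: list[tuple[str, Lexicon]] = []
        if ("F4a" in self.families or "F4b" in self.families) and self.train_lexicon is not None:
            out.append(("F4a", self.train_lexicon))
        if "F4b" in self.families and self.external_lexicon is not None:
            out.append(("F4b", self.external_lexicon))
        return out


def _window_texts(flat: Sequence[Token], i: int, radius: int) -> dict[int, str]:
    """Lowercased token texts at offsets -radius..+radius, padded at edges."""
    out: dict[int, str] = {}
    for off in range(-radius, radius + 1):
        j = i + off
        if j < 0:
            out[off] = PAD_LEFT
        elif j >= len(flat):
            out[off] = PAD_RIGHT
        else:
            out[off] = flat[j].text.lower()
    return out


def _shape(text: str) -> str:
    """Collapse a token into a character-class shape, e.g. 0.4 -> d.d."""
    shape = []
    for c in text:
        if c.isdigit():
            s = "d"
        elif c.isalpha():
            s = "X" if c.isupper() else "x"
        else:
            s = c
        if not shape or shape[-1] != s:
            shape.append(s)
    return "".join(shape)


def _cap_pattern(text: str) -> str:
    if text.isupper() and any(c.isalpha() for c in text):
        return "ALLCAPS"
    if text[:1].isupper():
        return "INITCAP"
    if text.islower():
        return "LOWER"
    if any(c.isupper() for c in text):
        return "MIXED"
    return "OTHER"


def _is_dose_pattern(tok: Token, flat: Sequence[Token], i: int) -> bool:
    """A number followed by a unit token, or a fused number+unit token."""
    text = tok.text.rstrip(",.;")
    if _NUM_UNIT_RE.match(text):
        return True
    if _NUM_RE.match(text) and i + 1 < len(flat):
        nxt = flat[i + 1].text.rstrip(",.;").lower()
        return nxt in _DOSE_UNITS
    return False


def _coord_index(doc: Document, flat: Sequence[Token]) -> dict[tuple[int, int], int]:
    """Coordinate -> reading-order index map, memoized on the document."""
    cached = getattr(doc, "_coord_index_cache", None)
    if cached is None or len(cached) != len(flat):
        cached = {t.coord: i for i, t in enumerate(flat)}
        doc._coord_index_cache = cached  # type: ignore[attr-defined]
    return cached


def _name_proximity_features(
    doc: Document,
    flat: Sequence[Token],
    index: int,
    name_spans: Sequence[FieldSpan],
    feats: dict[str, float],
) -> None:
    """Look-back and look-ahead proximity of the token to detected
    medication names, in the token stream and in lines.

    Non-name fields sit within a few tokens of their medication name,
    while lookalike phrases in plain narrative do not, so both the gap to
    the previous name and the look-ahead gap to the next one are emitted,
    alongside the signed line distance to the nearest name.
    """
    coord_index = _coord_index(doc, flat)
    tok = flat[index]
    prev_best: tuple[int, int] | None = None  # (stream gap, line delta)
    next_best: tuple[int, int] | None = None
    inside = False
    for span in name_spans:
        if not span.present:
            continue
        i_start = coord_index[span.start]
        i_end = coord_index[span.end]
        if i_start <= index <= i_end:
            inside = True
            continue
        if i_end < index:
            gap = index - i_end
            if prev_best is None or gap < prev_best[0]:
                prev_best = (gap, tok.line_no - span.start[0])
        else:
            gap = i_start - index
            if next_best is None or gap < next_best[0]:
                next_best = (gap, tok.line_no - span.start[0])
    if inside:
        feats["F2:name_inside"] = 1.0
        return
    nearest_dline: int | None = None
    for best, direction in ((prev_best, "prev"), (next_best, "next")):
        if best is None:
            continue
        gap, dline = best
        if dline == 0:
            feats[f"F2:name_{direction}_tok={bucket(gap)}"] = 1.0
        else:
            feats[f"F2:name_{direction}_line={bucket(abs(dline))}"] = 1.0
        if nearest_dline is None or abs(dline) < abs(nearest_dline):
            nearest_dline = dline
    if nearest_dline is not None:
        sign = "-" if nearest_dline < 0 else "+"
        feats[f"F2:name_dline={sign}{bucket(abs(nearest_dline))}"] = 1.0
        feats["F2:name_dline_raw"] = float(nearest_dline)


def extract_token_features(
    doc: Document,
    flat: Sequence[Token],
    index: int,
    prev_tags: Sequence[str],
    pos_labels: Mapping[tuple[int, int], str],
    config: FeatureConfig,
    name_spans: Sequence[FieldSpan] | None = None,
) -> dict[str, float]:
    """Feature vector for the token at ``flat[index]``.

    ``flat`` is the document's token stream in reading order (as produced
    by ``list(doc.iter_tokens())``); ``prev_tags`` are the IOB tags already
    assigned to ``flat[:index]`` (gold tags at training time, predictions
    at decoding time).  ``name_spans`` enables the name-proximity features
    of the non-name tagger and must be omitted for the single-pass tagger.
    """
    tok = flat[index]
    feats: dict[str, float] = {}
    w = _window_texts(flat, index, max(config.ngram_window, 2))
    radius = config.ngram_window

    if "F1" in config.families:
        for off in range(-radius, radius + 1):
            feats[f"F1:w[{off}]={w[off]}"] = 1.0
        for off in range(-radius, radius):
            feats[f"F1:w[{off}]w[{off + 1}]={w[off]}|{w[off + 1]}"] = 1.0
        for off in range(-radius, radius - 1):
            feats[f"F1:w[{off}]w[{off + 1}]w[{off + 2}]={w[off]}|{w[off + 1]}|{w[off + 2]}"] = 1.0

    if "F2" in config.families:
        for off in range(-radius, radius + 1):
            j = index + off
            if 0 <= j < len(flat):
                pos = pos_labels.get(flat[j].coord, "UNK")
            else:
                pos = PAD_LEFT if off < 0 else PAD_RIGHT
            feats[f"F2:pos[{off}]={pos}"] = 1.0
        low = tok.text.lower()
        for n in range(1, min(config.affix_max_len, len(low)) + 1):
            feats[f"F2:prefix{n}={low[:n]}"] = 1.0
            feats[f"F2:suffix{n}={low[-n:]}"] = 1.0
        feats[f"F2:len={bucket(len(tok.text))}"] = 1.0
        feats["F2:len_raw"] = float(len(tok.text))
        feats[f"F2:cap={_cap_pattern(tok.text)}"] = 1.0
        feats[f"F2:shape={_shape(tok.text)}"] = 1.0
        section = doc.section_of(tok.line_no)
        heading = section.heading if section is not None else ""
        feats[f"F2:section={heading or '<none>'}"] = 1.0
        if config.others_variant and _is_dose_pattern(tok, flat, index):
            feats["F2:dose_pattern"] = 1.0
        if name_spans is not None:
            _name_proximity_features(doc, flat, index, name_spans, feats)

    if "F3" in config.families:
        t1 = prev_tags[index - 1] if index >= 1 else PAD_LEFT
        t2 = prev_tags[index - 2] if index >= 2 else PAD_LEFT
        feats[f"F3:t[-1]={t1}"] = 1.0
        feats[f"F3:t[-2]t[-1]={t2}|{t1}"] = 1.0

    for prefix, lexicon in config.active_lexicons():
        if prefix not in config.families and not (prefix == "F4a" and "F4b" in config.families):
            continue
        cur = w[0]
        for n in range(1, 4):
            hit = False
            for start in range(-n + 1, 1):
                gram = tuple(w.get(start + k, PAD_RIGHT) for k in range(n))
                if cur in gram and lexicon.has_ngram(gram):
                    hit = True
                    break
            if hit:
                feats[f"{prefix}:{lexicon.name}:in_{n}gram"] = 1.0

    return feats


def extract_context_features(doc: Document, name_span: FieldSpan) -> dict[str, float]:
    """Features for the list/narrative context classifier of one detected
    medication name: its section, the comma and token counts of its line,
    the name itself and its line position, and nearby words."""
    if not name_span.present or name_span.field_type != "m":
        raise ValueError("context features require a present name span")
    line_no, start_idx = name_span.start
    line = doc.line_tokens(line_no)
    n_commas = sum(t.text.count(",") for t in line)
    feats: dict[str, float] = {}
    section = doc.section_of(line_no)
    heading = section.heading if section is not None else ""
    feats[f"ctx:section={heading or '<none>'}"] = 1.0
    feats["ctx:commas_raw"] = float(n_commas)
    feats[f"ctx:commas={bucket(n_commas)}"] = 1.0
    feats["ctx:line_tokens_raw"] = float(len(line))
    feats[f"ctx:line_tokens={bucket(len(line))}"] = 1.0
    feats[f"ctx:name={name_span.text}"] = 1.0
    feats["ctx:position_raw"] = float(start_idx)
    feats[f"ctx:position={bucket(start_idx)}"] = 1.0
    flat = list(doc.iter_tokens())
    coords = [t.coord for t in flat]
    first = coords.index((line_no, start_idx))
    last = coords.index(name_span.end)
    for off in (-2, -1):
        j = first + off
        feats[f"ctx:w[{off}]={flat[j].text.lower() if j >= 0 else PAD_LEFT}"] = 1.0
    for off in (1, 2):
        j = last + off
        feats[f"ctx:w[+{off}]={flat[j].text.lower() if j < len(flat) else PAD_RIGHT}"] = 1.0
    return feats


def build_training_lexicon(gold: Iterable[tuple[Document, Sequence]]) -> Lexicon:
    """Lexicon of all gold medication-name texts in a training corpus."""
    names: set[str] = set()
    for _doc, entries in gold:
        for entry in entries:
            names.add(entry.name.text)
    return Lexicon(name="train", entries=frozenset(names))


def load_external_lexicon(path: "str | Path", name: str = "external") -> Lexicon:
    """Load a one-name-per-line drug list, normalized and deduplicated."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read lexicon file {path}: {exc}") from exc
    return Lexicon.from_names(name, text.splitlines())
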