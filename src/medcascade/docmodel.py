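"""Document model, tokenization, section segmentation, POS tagging, and
reader/writer for the medication-entry annotation format.

Coordinate convention
---------------------
A token is addressed as ``line:token`` where lines are numbered from 1
(blank lines count) and tokens are the 0-based whitespace-delimited tokens
of their line.  Span ends are inclusive, so a single-token field has equal
start and end coordinates, e.g. ``57:6 57:6``.

Annotation format
-----------------
One medication entry per line, fields separated by ``||``::

    m="nitroglycerin" 58:0 58:0||do="nm"||mo="sublingual" 57:6 57:6||...||ln="narrative"

A field is either ``key="text" L:T L:T`` (present) or ``key="nm"``
(not mentioned).  Both straight and typographic quotes are accepted on
input; output always uses straight quotes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

FIELD_TYPES = ("m", "do", "mo", "f", "du", "r")
NON_NAME_TYPES = ("do", "mo", "f", "du", "r")
CONTEXT_LABELS = ("list", "narrative")

#: literal marking a field that is not mentioned for an entry
ABSENT = "nm"

_QUOTES = "\"“”„″˝"
_TRAILING_PUNCT = ",.;"


@dataclass(frozen=True)
class Token:
    """A whitespace token with its line:token coordinates."""

    text: str
    line_no: int  # 1-based
    token_idx: int  # 0-based within the line

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise ValueError(f"token text must be non-empty and whitespace-free: {self.text!r}")

    @property
    def coord(self) -> tuple[int, int]:
        return (self.line_no, self.token_idx)


@dataclass(frozen=True)
class Section:
    """A contiguous block of lines under one heading.

    ``heading`` is empty for the anonymous block before the first detected
    heading.  ``excluded`` marks sections (e.g. FAMILY HISTORY) whose
    medication mentions must not appear in system output.
    """

    heading: str
    start_line: int
    end_line: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.start_line > self.end_line:
            raise ValueError(f"section {self.heading!r}: start {self.start_line} > end {self.end_line}")

    def contains(self, line_no: int) -> bool:
        return self.start_line <= line_no <= self.end_line


@dataclass(frozen=True)
class SectionConfig:
    """Configuration for heading collection and section exclusion."""

    heading_frequency_threshold: int = 3
    excluded_headings: frozenset[str] = frozenset({"FAMILY HISTORY", "ALLERGIES"})

    def __post_init__(self) -> None:
        if self.heading_frequency_threshold < 1:
            raise ValueError("heading_frequency_threshold must be >= 1")

    def is_excluded(self, heading: str) -> bool:
        return heading.strip().upper() in {h.upper() for h in self.excluded_headings}


@dataclass
class Document:
    """A tokenized note: ordered lines of tokens plus optional sections."""

    doc_id: str
    lines: list[list[Token]]
    sections: list[Section] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def line_tokens(self, line_no: int) -> list[Token]:
        """Tokens of a 1-based line number."""
        return self.lines[line_no - 1]

    def token_at(self, line_no: int, token_idx: int) -> Token:
        return self.lines[line_no - 1][token_idx]

    def iter_tokens(self) -> Iterator[Token]:
        for line in self.lines:
            yield from line

    def tokens_in_span(self, start: tuple[int, int], end: tuple[int, int]) -> list[Token]:
        """All tokens between two inclusive line:token coordinates."""
        out: list[Token] = []
        for line_no in range(start[0], end[0] + 1):
            for tok in self.line_tokens(line_no):
                lo = start[1] if line_no == start[0] else 0
                hi = end[1] if line_no == end[0] else len(self.line_tokens(line_no)) - 1
                if lo <= tok.token_idx <= hi:
                    out.append(tok)
        return out

    def section_of(self, line_no: int) -> Section | None:
        for sec in self.sections:
            if sec.contains(line_no):
                return sec
        return None


@dataclass(frozen=True)
class FieldSpan:
    """One typed medication field, or the "nm" marker for an absent slot."""

    field_type: str
    text: str
    start: tuple[int, int] | None = None
    end: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.field_type not in FIELD_TYPES:
            raise ValueError(f"unknown field type {self.field_type!r}")
        if self.present:
            if self.start is None or self.end is None:
                raise ValueError("present field requires start and end coordinates")
            if self.start > self.end:
                raise ValueError(f"span start {self.start} after end {self.end}")
            if not self.text:
                raise ValueError("present field requires non-empty text")

    @property
    def present(self) -> bool:
        return self.text != ABSENT

    @classmethod
    def absent(cls, field_type: str) -> "FieldSpan":
        return cls(field_type=field_type, text=ABSENT)


@dataclass(frozen=True)
class Entry:
    """A medication event: a name field, five non-name slots, and the
    list/narrative context label ``ln``."""

    name: FieldSpan
    do: FieldSpan
    mo: FieldSpan
    f: FieldSpan
    du: FieldSpan
    r: FieldSpan
    ln: str

    def __post_init__(self) -> None:
        if self.name.field_type != "m" or not self.name.present:
            raise ValueError("entry requires a present name field of type m")
        for ftype in NON_NAME_TYPES:
            slot = getattr(self, ftype)
            if slot.field_type != ftype:
                raise ValueError(f"slot {ftype} holds a field of type {slot.field_type}")
        if self.ln not in CONTEXT_LABELS:
            raise ValueError(f"ln must be one of {CONTEXT_LABELS}, got {self.ln!r}")

    @classmethod
    def build(cls, name: FieldSpan, ln: str, **slots: FieldSpan) -> "Entry":
        """Create an entry filling unspecified non-name slots with "nm"."""
        filled = {t: slots.get(t, FieldSpan.absent(t)) for t in NON_NAME_TYPES}
        return cls(name=name, ln=ln, **filled)

    def present_fields(self) -> list[FieldSpan]:
        """The name plus every present non-name field."""
        out = [self.name]
        out.extend(getattr(self, t) for t in NON_NAME_TYPES if getattr(self, t).present)
        return out


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize_document(raw_text: str, doc_id: str = "") -> Document:
    """Split line-oriented text into whitespace tokens with coordinates.

    Lines are numbered from 1 and blank lines are kept (as empty token
    sequences) so that line numbers in annotations match the source file.
    Punctuation stays attached to its token: the annotation format
    addresses whitespace tokens, so ``mg,`` is a single token.
    """
    lines: list[list[Token]] = []
    for i, line in enumerate(raw_text.split("\n"), start=1):
        lines.append([Token(t, i, j) for j, t in enumerate(line.split())])
    # a trailing newline produces a spurious final empty line
    if lines and not lines[-1] and raw_text.endswith("\n"):
        lines.pop()
    return Document(doc_id=doc_id, lines=lines)


# ---------------------------------------------------------------------------
# Section segmentation
# ---------------------------------------------------------------------------

#: a line starting with capitalized letters (possibly several words)
#: followed by a colon
_HEADING_RE = re.compile(r"^([A-Z][A-Z ]*?)\s*:")


def match_heading(line_text: str) -> str | None:
    """Return the heading string if the line starts with one, else None."""
    m = _HEADING_RE.match(line_text)
    if m is None:
        return None
    heading = m.group(1).strip()
    return heading or None


def collect_headings(corpus: Iterable[str], config: SectionConfig | None = None) -> set[str]:
    """Collect candidate section headings whose corpus frequency exceeds
    the configured threshold.

    A candidate is a line starting with a run of capitalized letters
    followed by a colon; its frequency is the number of lines (over the
    whole corpus) on which it occurs.
    """
    config = config or SectionConfig()
    counts: dict[str, int] = {}
    for raw_text in corpus:
        for line in raw_text.split("\n"):
            heading = match_heading(line)
            if heading is not None:
                counts[heading] = counts.get(heading, 0) + 1
    return {h for h, c in counts.items() if c > config.heading_frequency_threshold}


def segment_sections(
    doc: Document,
    headings: set[str],
    config: SectionConfig | None = None,
    line_texts: Sequence[str] | None = None,
) -> Document:
    """Attach sections to a document using a heading lexicon.

    Each heading occurrence opens a section that runs to the line before
    the next heading (or end of document).  Lines before the first heading
    form an anonymous, never-excluded section.  ``excluded`` is set from
    the config's exclusion list; the excluded headings themselves are
    always recognized even when too rare for the frequency-based lexicon,
    since the exclusion list is fixed by the annotation guidelines rather
    than learned from data.
    """
    config = config or SectionConfig()
    if line_texts is None:
        line_texts = [" ".join(t.text for t in line) for line in doc.lines]
    known = set(headings) | {h.strip().upper() for h in config.excluded_headings}
    starts: list[tuple[int, str]] = []
    for line_no, text in enumerate(line_texts, start=1):
        heading = match_heading(text)
        if heading is not None and heading in known:
            starts.append((line_no, heading))

    sections: list[Section] = []
    if doc.n_lines == 0:
        doc.sections = sections
        return doc
    first = starts[0][0] if starts else doc.n_lines + 1
    if first > 1:
        sections.append(Section(heading="", start_line=1, end_line=min(first - 1, doc.n_lines)))
    for k, (line_no, heading) in enumerate(starts):
        end = starts[k + 1][0] - 1 if k + 1 < len(starts) else doc.n_lines
        sections.append(
            Section(heading=heading, start_line=line_no, end_line=end,
                    excluded=config.is_excluded(heading))
        )
    doc.sections = sections
    return doc


# ---------------------------------------------------------------------------
# POS tagging
# ---------------------------------------------------------------------------

class RegexPosTagger:
    """Deterministic fallback POS tagger built from closed-class word
    tables, suffix rules, and shape rules.

    Coarse but adequate as a feature source: the taggers only consume POS
    labels as categorical features, so consistency matters more than
    linguistic fidelity.  Any Penn-style tagger can be plugged in instead.
    """

    _CLOSED: dict[str, str] = {
        "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
        "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "we": "PRP",
        "his": "PRP$", "her": "PRP$", "their": "PRP$",
        "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN",
        "without": "IN", "to": "TO", "at": "IN", "by": "IN", "as": "IN",
        "is": "VBZ", "was": "VBD", "were": "VBD", "are": "VBP", "be": "VB",
        "took": "VBD", "takes": "VBZ", "take": "VB", "had": "VBD", "has": "VBZ",
        "and": "CC", "or": "CC", "but": "CC",
        "not": "RB", "no": "DT",
    }
    _NUM_RE = re.compile(r"^[0-9][0-9.,:/\-]*$|^[0-9.,:/\-]*[0-9]$")
    _PUNCT_RE = re.compile(r"^[^\w]+$")

    def tag_line(self, tokens: Sequence[str]) -> list[str]:
        return [self.tag_token(t) for t in tokens]

    def tag_token(self, text: str) -> str:
        core = text.rstrip(_TRAILING_PUNCT)
        word = core or text
        low = word.lower()
        if low in self._CLOSED:
            return self._CLOSED[low]
        if self._NUM_RE.match(word):
            return "CD"
        if self._PUNCT_RE.match(text):
            return "."
        if low.endswith("ing"):
            return "VBG"
        if low.endswith("ed"):
            return "VBD"
        if low.endswith("ly"):
            return "RB"
        if low.endswith(("tion", "ment", "ness", "ity", "sion")):
            return "NN"
        if low.endswith(("ous", "ful", "ive", "al", "ic")):
            return "JJ"
        if word[:1].isupper():
            return "NNP"
        return "NN"


PosTagger = Callable[[Sequence[str]], Sequence[str]]


def pos_tag(doc: Document, tagger: "RegexPosTagger | PosTagger | None" = None) -> dict[tuple[int, int], str]:
    """POS-tag a document, returning a coordinate -> label map.

    The tagger is pluggable: anything mapping a line's token texts to one
    label per token works.  A line on which the tagger fails (raises, or
    returns the wrong number of labels) gets "UNK" for all its tokens.
    """
    if tagger is None:
        tagger = RegexPosTagger()
    tag_line = tagger.tag_line if isinstance(tagger, RegexPosTagger) else tagger
    labels: dict[tuple[int, int], str] = {}
    for line in doc.lines:
        texts = [t.text for t in line]
        try:
            tags = list(tag_line(texts))
            if len(tags) != len(texts):
                raise ValueError("tagger returned wrong label count")
        except Exception:
            tags = ["UNK"] * len(texts)
        for tok, tag in zip(line, tags):
            labels[tok.coord] = tag
    return labels


# ---------------------------------------------------------------------------
# Field-text normalization
# ---------------------------------------------------------------------------

def normalize_field_text(tokens: Iterable["Token | str"]) -> str:
    """Normalize the tokens of a field span into its annotation text.

    Each token is lowercased and stripped of trailing ``, . ;`` (the gold
    convention: the span covering ``mg,`` reads ``0.4 mg``).  A token that
    reduces to nothing (all punctuation) is kept as its raw lowercased
    form.  Tokens are joined by single spaces.
    """
    parts: list[str] = []
    for tok in tokens:
        text = tok.text if isinstance(tok, Token) else tok
        low = text.lower()
        stripped = low.rstrip(_TRAILING_PUNCT)
        parts.append(stripped if stripped else low)
    if not parts:
        raise ValueError("normalize_field_text requires at least one token")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Annotation format reader/writer
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^(\d+):(\d+)$")


class AnnotationFormatError(ValueError):
    """Raised for malformed entry-annotation records."""


def _parse_field(chunk: str, record_no: int) -> tuple[str, str, tuple[int, int] | None, tuple[int, int] | None]:
    chunk = chunk.strip()
    eq = chunk.find("=")
    if eq < 0:
        raise AnnotationFormatError(f"record {record_no}: field without '=': {chunk!r}")
    key = chunk[:eq].strip()
    rest = chunk[eq + 1:].strip()
    if not rest or rest[0] not in _QUOTES:
        raise AnnotationFormatError(f"record {record_no}: unquoted value in {chunk!r}")
    close = -1
    for i in range(len(rest) - 1, 0, -1):
        if rest[i] in _QUOTES:
            close = i
            break
    if close <= 0:
        raise AnnotationFormatError(f"record {record_no}: unterminated quote in {chunk!r}")
    text = rest[1:close]
    coord_part = rest[close + 1:].split()
    if not coord_part:
        return key, text, None, None
    if len(coord_part) != 2:
        raise AnnotationFormatError(
            f"record {record_no}: expected two coordinates after {key}, got {coord_part!r}")
    coords = []
    for c in coord_part:
        m = _COORD_RE.match(c)
        if m is None:
            raise AnnotationFormatError(f"record {record_no}: malformed coordinate {c!r}")
        coords.append((int(m.group(1)), int(m.group(2))))
    return key, text, coords[0], coords[1]


def parse_entries(annotation_text: str) -> list[Entry]:
    """Parse the entry annotation format (one record per non-blank line).

    Field text is re-normalized through :func:`normalize_field_text`, so
    parsed text always matches what the coordinates address under the
    package's normalization.
    """
    entries: list[Entry] = []
    record_no = 0
    for raw_line in annotation_text.split("\n"):
        if not raw_line.strip():
            continue
        record_no += 1
        seen: dict[str, FieldSpan] = {}
        ln: str | None = None
        for chunk in raw_line.split("||"):
            if not chunk.strip():
                continue
            key, text, start, end = _parse_field(chunk, record_no)
            if key == "ln":
                if text not in CONTEXT_LABELS:
                    raise AnnotationFormatError(
                        f"record {record_no}: ln must be list or narrative, got {text!r}")
                ln = text
                continue
            if key not in FIELD_TYPES:
                raise AnnotationFormatError(f"record {record_no}: unknown field key {key!r}")
            if key in seen:
                raise AnnotationFormatError(f"record {record_no}: duplicate field {key!r}")
            if text == ABSENT:
                seen[key] = FieldSpan.absent(key)
            else:
                if start is None or end is None:
                    raise AnnotationFormatError(
                        f"record {record_no}: present field {key} lacks coordinates")
                seen[key] = FieldSpan(
                    field_type=key,
                    text=normalize_field_text(text.split()),
                    start=start,
                    end=end,
                )
        if "m" not in seen or not seen["m"].present:
            raise AnnotationFormatError(f"record {record_no}: missing or absent name field")
        if ln is None:
            raise AnnotationFormatError(f"record {record_no}: missing ln label")
        entries.append(Entry.build(seen["m"], ln, **{k: v for k, v in seen.items() if k != "m"}))
    return entries


def _format_field(span: FieldSpan) -> str:
    if not span.present:
        return f'{span.field_type}="{ABSENT}"'
    s, e = span.start, span.end
    return f'{span.field_type}="{span.text}" {s[0]}:{s[1]} {e[0]}:{e[1]}'


def write_entries(entries: Sequence[Entry]) -> str:
    """Serialize entries canonically: fields in m, do, mo, f, du, r, ln
    order, straight quotes, one record per line.

    The canonical form is a fixed point of parse/write.
    """
    records = []
    for entry in entries:
        parts = [_format_field(entry.name)]
        parts.extend(_format_field(getattr(entry, t)) for t in NON_NAME_TYPES)
        parts.append(f'ln="{entry.ln}"')
        records.append("||".join(parts))
    return "\n".join(records) + ("\n" if records else "")
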