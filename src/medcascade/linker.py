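"""Heuristic linking of detected fields into medication entries.

Each non-name field is linked to either the closest prior or closest
subsequent medication name.  The prior name wins by default; the
subsequent name wins only when it is closer by more than a margin
(default two lines), or when no prior name exists.  Distances are
measured in lines between span starts.  Fields of the same type linked
to one name are distributed across as many entries as the maximum
per-type multiplicity, nearest field first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from medcascade.docmodel import NON_NAME_TYPES, Entry, FieldSpan


@dataclass(frozen=True)
class LinkConfig:
    """``subsequent_override_margin``: how many lines closer (strictly
    more than this) a subsequent name must be to beat the prior name."""

    subsequent_override_margin: int = 2

    def __post_init__(self) -> None:
        if self.subsequent_override_margin < 0:
            raise ValueError("margin must be >= 0")


def _line_distance(a: FieldSpan, b: FieldSpan) -> int:
    return abs(a.start[0] - b.start[0])


def _doc_order_key(span: FieldSpan) -> tuple[int, int]:
    return span.start


def link_fields(
    names: Sequence[FieldSpan],
    others: Sequence[FieldSpan],
    config: LinkConfig | None = None,
) -> dict[int, int]:
    """Link each non-name field to a name field.

    Returns a mapping from index into ``others`` to index into ``names``.
    Fields in a document with no names at all are discarded (absent from
    the mapping).
    """
    config = config or LinkConfig()
    margin = config.subsequent_override_margin
    ordered = sorted(range(len(names)), key=lambda i: _doc_order_key(names[i]))
    links: dict[int, int] = {}
    if not names:
        return links
    for oi, other in enumerate(others):
        prior = None
        subsequent = None
        for ni in ordered:
            if _doc_order_key(names[ni]) <= _doc_order_key(other):
                prior = ni
            elif subsequent is None:
                subsequent = ni
        if prior is None and subsequent is None:
            continue
        if prior is None:
            links[oi] = subsequent  # type: ignore[assignment]
        elif subsequent is None:
            links[oi] = prior
        else:
            d_prior = _line_distance(other, names[prior])
            d_sub = _line_distance(other, names[subsequent])
            links[oi] = subsequent if d_sub < d_prior - margin else prior
    return links


def assemble_entries(
    name: FieldSpan,
    ln: str,
    linked: Sequence[FieldSpan],
) -> list[Entry]:
    """Build entries from one name and the non-name fields linked to it.

    With k the maximum multiplicity over the five non-name types, k
    entries are emitted (at least one), all sharing the name and ln.
    Within each type, fields are ordered by absolute line distance from
    the name (token distance breaks ties), and the i-th nearest goes into
    entry i; unfilled slots stay "nm".
    """
    by_type: dict[str, list[FieldSpan]] = {t: [] for t in NON_NAME_TYPES}
    for span in linked:
        if span.field_type not in by_type:
            raise ValueError(f"non-name field expected, got type {span.field_type!r}")
        by_type[span.field_type].append(span)
    for t in by_type:
        by_type[t].sort(key=lambda s: (
            abs(s.start[0] - name.start[0]),
            abs(s.start[1] - name.start[1]),
            s.start,
        ))
    k = max((len(v) for v in by_type.values()), default=0) or 1
    entries = []
    for i in range(k):
        slots = {t: by_type[t][i] for t in NON_NAME_TYPES if i < len(by_type[t])}
        entries.append(Entry.build(name, ln, **slots))
    return entries


def link_and_assemble(
    names_with_ln: Sequence[tuple[FieldSpan, str]],
    others: Sequence[FieldSpan],
    config: LinkConfig | None = None,
) -> list[Entry]:
    """Full linking step: link every non-name field, then assemble the
    entries of each name in document order."""
    names = [n for n, _ in names_with_ln]
    links = link_fields(names, others, config)
    grouped: dict[int, list[FieldSpan]] = {i: [] for i in range(len(names))}
    for oi, ni in links.items():
        grouped[ni].append(others[oi])
    order = sorted(range(len(names)), key=lambda i: _doc_order_key(names[i]))
    entries: list[Entry] = []
    for ni in order:
        name, ln = names_with_ln[ni]
        entries.extend(assemble_entries(name, ln, grouped[ni]))
    return entries
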