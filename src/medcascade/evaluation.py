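"""Exact-match scoring and significance testing.

Two granularities are reported.  *Vertical* metrics score individual
fields: a system field is a true positive when a gold field with the same
type and identical span coordinates exists.  *Horizontal* metrics score
whole entries: a system entry matches a gold entry only when all six
field slots agree (absent slots on both sides, present slots exact
matches); the context label ln is not part of the match by default and is
scored separately as context accuracy.

System differences are tested with an approximate randomization test:
the two systems' per-document outputs are swapped with probability 0.5,
the corpus-level F-score difference recomputed, and the p-value estimated
as (i+1)/(n+1) over n shuffles, with a Bonferroni correction available
for families of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from medcascade.docmodel import FIELD_TYPES, NON_NAME_TYPES, Entry, FieldSpan


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F as percentages, with the underlying counts."""

    tp: int
    n_system: int
    n_gold: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / self.n_system if self.n_system else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.n_system + other.n_system, self.n_gold + other.n_gold)


@dataclass
class MetricReport:
    """Horizontal and vertical exact-match scores for one comparison."""

    horizontal: PRF
    vertical_by_type: dict[str, PRF]
    vertical_all: PRF
    context_accuracy: float | None = None

    def format_table(self) -> str:
        rows = [("", "Precision", "Recall", "F-score")]
        label = {"m": "Name", "do": "Dosage", "f": "Frequency", "mo": "Mode",
                 "du": "Duration", "r": "Reason"}
        for t in FIELD_TYPES:
            prf = self.vertical_by_type.get(t, PRF(0, 0, 0))
            rows.append((label[t], f"{prf.precision:.1f}", f"{prf.recall:.1f}", f"{prf.f:.1f}"))
        rows.append(("All fields", f"{self.vertical_all.precision:.1f}",
                     f"{self.vertical_all.recall:.1f}", f"{self.vertical_all.f:.1f}"))
        rows.append(("Horizontal", f"{self.horizontal.precision:.1f}",
                     f"{self.horizontal.recall:.1f}", f"{self.horizontal.f:.1f}"))
        widths = [max(len(r[c]) for r in rows) for c in range(4)]
        lines = ["  ".join(r[c].ljust(widths[c]) for c in range(4)).rstrip() for r in rows]
        if self.context_accuracy is not None:
            lines.append(f"Context accuracy  {self.context_accuracy:.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def prf_dict(p: PRF) -> dict:
            return {"precision": round(p.precision, 1), "recall": round(p.recall, 1),
                    "f": round(p.f, 1), "tp": p.tp, "n_system": p.n_system, "n_gold": p.n_gold}
        out = {
            "horizontal": prf_dict(self.horizontal),
            "vertical": {t: prf_dict(v) for t, v in self.vertical_by_type.items()},
            "vertical_all": prf_dict(self.vertical_all),
        }
        if self.context_accuracy is not None:
            out["context_accuracy"] = round(self.context_accuracy, 1)
        return out


@dataclass(frozen=True)
class RandTestResult:
    """Outcome of one approximate randomization comparison."""

    observed_diff: float
    i: int
    n: int
    p: float
    adjusted_alpha: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        threshold = self.adjusted_alpha if self.adjusted_alpha is not None else alpha
        return self.p < threshold


def field_exact_match(a: FieldSpan, b: FieldSpan) -> bool:
    """Exact match: identical start, end, and field type (text is derived
    from the span, so it is not compared)."""
    if not a.present or not b.present:
        return False
    return a.field_type == b.field_type and a.start == b.start and a.end == b.end


def _field_key(span: FieldSpan) -> tuple[str, tuple[int, int], tuple[int, int]]:
    return (span.field_type, span.start, span.end)


def _dedup_fields(entries: Sequence[Entry]) -> set[tuple]:
    """Unique (type, start, end) triples over all entry fields; entries
    sharing a field (multi-entry names) contribute it once."""
    keys: set[tuple] = set()
    for entry in entries:
        for span in entry.present_fields():
            keys.add(_field_key(span))
    return keys


def score_vertical(
    system: Mapping[str, Sequence[Entry]],
    gold: Mapping[str, Sequence[Entry]],
) -> tuple[dict[str, PRF], PRF]:
    """Field-level exact-match scores per field type and pooled.

    ``system`` and ``gold`` map document ids to entry lists; fields are
    deduplicated by (type, span) within each document.
    """
    per_type = {t: PRF(0, 0, 0) for t in FIELD_TYPES}
    for doc_id in set(system) | set(gold):
        sys_keys = _dedup_fields(system.get(doc_id, ()))
        gold_keys = _dedup_fields(gold.get(doc_id, ()))
        for t in FIELD_TYPES:
            s = {k for k in sys_keys if k[0] == t}
            g = {k for k in gold_keys if k[0] == t}
            per_type[t] = per_type[t] + PRF(len(s & g), len(s), len(g))
    pooled = sum(per_type.values(), PRF(0, 0, 0))
    return per_type, pooled


def entries_match(a: Entry, b: Entry, include_ln: bool = False) -> bool:
    """Horizontal match: every field slot agrees."""
    if not field_exact_match(a.name, b.name):
        return False
    for t in NON_NAME_TYPES:
        sa, sb = getattr(a, t), getattr(b, t)
        if sa.present != sb.present:
            return False
        if sa.present and not field_exact_match(sa, sb):
            return False
    if include_ln and a.ln != b.ln:
        return False
    return True


def _count_entry_matches(
    system: Sequence[Entry], gold: Sequence[Entry], include_ln: bool
) -> int:
    """Greedy one-to-one matching in document order."""
    used = [False] * len(gold)
    matches = 0
    for s in system:
        for j, g in enumerate(gold):
            if not used[j] and entries_match(s, g, include_ln):
                used[j] = True
                matches += 1
                break
    return matches


def score_horizontal(
    system: Mapping[str, Sequence[Entry]],
    gold: Mapping[str, Sequence[Entry]],
    include_ln: bool = False,
) -> PRF:
    """Entry-level exact-match scores over a document collection."""
    total = PRF(0, 0, 0)
    for doc_id in set(system) | set(gold):
        s = list(system.get(doc_id, ()))
        g = list(gold.get(doc_id, ()))
        total = total + PRF(_count_entry_matches(s, g, include_ln), len(s), len(g))
    return total


def score_context_accuracy(
    system: Mapping[str, Sequence[Entry]],
    gold: Mapping[str, Sequence[Entry]],
) -> float:
    """Accuracy of the list/narrative label over name-matched entries."""
    correct = 0
    total = 0
    for doc_id in set(system) & set(gold):
        gold_by_name = {_field_key(g.name): g.ln for g in gold[doc_id]}
        for s in system[doc_id]:
            ln = gold_by_name.get(_field_key(s.name))
            if ln is not None:
                total += 1
                correct += ln == s.ln
    return 100.0 * correct / total if total else 0.0


def full_report(
    system: Mapping[str, Sequence[Entry]],
    gold: Mapping[str, Sequence[Entry]],
    include_ln: bool = False,
    with_context_accuracy: bool = False,
) -> MetricReport:
    by_type, pooled = score_vertical(system, gold)
    report = MetricReport(
        horizontal=score_horizontal(system, gold, include_ln),
        vertical_by_type=by_type,
        vertical_all=pooled,
    )
    if with_context_accuracy:
        report.context_accuracy = score_context_accuracy(system, gold)
    return report


# ---------------------------------------------------------------------------
# Approximate randomization
# ---------------------------------------------------------------------------

def approx_randomization_test(
    outputs_a: Mapping[str, Sequence[Entry]],
    outputs_b: Mapping[str, Sequence[Entry]],
    gold: Mapping[str, Sequence[Entry]],
    n: int = 10_000,
    seed: int = 0,
    include_ln: bool = False,
    exhaustive: bool = False,
) -> RandTestResult:
    """Stratified-shuffling significance test on horizontal F-score.

    For each of n shuffles, every document's two system outputs are
    swapped with probability 0.5 and the absolute corpus F-difference of
    the pseudo-systems recomputed; i counts shuffles whose difference is
    at least the observed one, and p = (i+1)/(n+1).  With ``exhaustive``
    all 2^D swap patterns are enumerated instead and p is the exact
    fraction (documents must be few).

    Per-document match counts are precomputed once, so each shuffle is a
    constant-size aggregation.
    """
    if set(outputs_a) != set(outputs_b):
        raise ValueError("the two systems must cover the same document set")
    if n < 1:
        raise ValueError("n must be >= 1")
    doc_ids = sorted(set(outputs_a) | set(gold))
    counts = np.zeros((len(doc_ids), 5), dtype=float)  # mA, sA, mB, sB, g
    for d, doc_id in enumerate(doc_ids):
        a = list(outputs_a.get(doc_id, ()))
        b = list(outputs_b.get(doc_id, ()))
        g = list(gold.get(doc_id, ()))
        counts[d] = (
            _count_entry_matches(a, g, include_ln), len(a),
            _count_entry_matches(b, g, include_ln), len(b), len(g),
        )
    m_a, s_a, m_b, s_b, g_n = counts.T
    total_gold = g_n.sum()

    def diff(swap: np.ndarray) -> np.ndarray:
        # swap: (n_shuffles, n_docs) booleans; True sends doc's A output to pseudo-B
        pm_a = np.where(swap, m_b, m_a).sum(axis=1)
        ps_a = np.where(swap, s_b, s_a).sum(axis=1)
        pm_b = np.where(swap, m_a, m_b).sum(axis=1)
        ps_b = np.where(swap, s_a, s_b).sum(axis=1)
        f = np.empty((2, len(pm_a)))
        for row, (pm, ps) in enumerate(((pm_a, ps_a), (pm_b, ps_b))):
            p = np.divide(pm, ps, out=np.zeros_like(pm), where=ps > 0)
            r = pm / total_gold if total_gold else np.zeros_like(pm)
            denom = p + r
            f[row] = np.divide(200.0 * p * r, denom, out=np.zeros_like(p), where=denom > 0)
        return np.abs(f[0] - f[1])

    observed = diff(np.zeros((1, len(doc_ids)), dtype=bool))[0]
    if exhaustive:
        if len(doc_ids) > 20:
            raise ValueError("exhaustive enumeration limited to 20 documents")
        patterns = np.array(
            [[(k >> d) & 1 for d in range(len(doc_ids))] for k in range(2 ** len(doc_ids))],
            dtype=bool,
        )
        diffs = diff(patterns)
        i = int(np.sum(diffs >= observed - 1e-12))
        return RandTestResult(observed_diff=float(observed), i=i, n=len(patterns),
                              p=i / len(patterns))
    rng = np.random.default_rng(seed)
    swaps = rng.random((n, len(doc_ids))) < 0.5
    diffs = diff(swaps)
    i = int(np.sum(diffs >= observed - 1e-12))
    p = (i + 1) / (n + 1)
    return RandTestResult(observed_diff=float(observed), i=i, n=n, p=p)


def bonferroni(alpha: float, m: int) -> float:
    """Corrected per-comparison threshold alpha/m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m
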