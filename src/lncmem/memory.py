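"""Eight-class dehydration-stress-memory typing.

A feature's transcriptional behaviour across two dehydration stresses is
summarized by a pair of response symbols: s1 for the D1-vs-C1 contrast
and s2 for the D2-vs-D1 contrast, each in {+, -, =}.  The eight types
[+/+], [+/-], [-/+], [-/-], [+/=], [-/=], [=/+], [=/-] cover every pair
with at least one non-"=" symbol; (=, =) features were never
differentially expressed and are typed ``none``.

Categories: the four types whose first symbol is non-"=" and second
symbol is non-"=" ([+/+], [+/-], [-/+], [-/-]) are *memory* — the
response changed (or repeated) between stresses; [+/=] and [-/=] are
*non-memory*; [=/+] and [=/-] are *late-response*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import ValidationError
from .diffexpr import DERecord
from ._util import round_half_up

__all__ = [
    "MEMORY_TYPES",
    "NON_MEMORY_TYPES",
    "LATE_RESPONSE_TYPES",
    "MemoryCall",
    "MemoryTable",
    "classify_memory",
    "call_memory",
    "tabulate_memory",
    "write_memory_table",
]

MEMORY_TYPES = ("[+/+]", "[+/-]", "[-/+]", "[-/-]")
NON_MEMORY_TYPES = ("[+/=]", "[-/=]")
LATE_RESPONSE_TYPES = ("[=/+]", "[=/-]")
ALL_TYPES = MEMORY_TYPES + NON_MEMORY_TYPES + LATE_RESPONSE_TYPES

_SYMBOLS = ("+", "-", "=")


@dataclass(frozen=True)
class MemoryCall:
    feature_id: str
    s1: str
    s2: str
    mtype: str
    category: str


def classify_memory(s1: str, s2: str) -> tuple[str, str]:
    """Map a (D1/C1, D2/D1) symbol pair to (mtype, category).

    The nine possible pairs map onto exactly the eight named types plus
    ``none`` (for (=, =)).
    """
    if s1 not in _SYMBOLS or s2 not in _SYMBOLS:
        raise ValidationError(f"symbols must be in {_SYMBOLS}, got ({s1!r}, {s2!r})")
    if s1 == "=" and s2 == "=":
        return "none", "none"
    mtype = f"[{s1}/{s2}]"
    if mtype in MEMORY_TYPES:
        return mtype, "memory"
    if mtype in NON_MEMORY_TYPES:
        return mtype, "non-memory"
    return mtype, "late-response"


def call_memory(
    de_d1c1: Sequence[DERecord], de_d2d1: Sequence[DERecord]
) -> list[MemoryCall]:
    """One MemoryCall per feature from the two contrasts' DE records.

    Both lists must cover the same feature set and carry contrasts
    (D1, C1) and (D2, D1) respectively; output is ordered by feature_id.
    """
    for recs, expected in ((de_d1c1, ("D1", "C1")), (de_d2d1, ("D2", "D1"))):
        wrong = {r.contrast for r in recs} - {expected}
        if wrong:
            raise ValidationError(
                f"expected contrast {expected}, found {sorted(wrong)}")
    m1 = {r.feature_id: r for r in de_d1c1}
    m2 = {r.feature_id: r for r in de_d2d1}
    if set(m1) != set(m2):
        only = sorted(set(m1) ^ set(m2))
        raise ValidationError(
            f"feature sets differ between contrasts ({len(only)} features, "
            f"first: {only[:3]})")
    calls = []
    for fid in sorted(m1):
        s1, s2 = m1[fid].symbol, m2[fid].symbol
        mtype, category = classify_memory(s1, s2)
        calls.append(MemoryCall(fid, s1, s2, mtype, category))
    return calls


@dataclass(frozen=True)
class MemoryTable:
    """Counts per type plus percentages.

    ``fractions`` reports the four memory types as percentages of
    ``total_memory`` and the non-memory/late-response types as
    percentages of all typed (non-``none``) features, each rounded
    half-up to one decimal.  ``empty`` flags an all-zero table whose
    fractions are reported as 0.
    """

    counts: Mapping[str, int]
    total_memory: int
    fractions: Mapping[str, float]
    empty: bool = False


def tabulate_memory(
    calls: Sequence[MemoryCall] | Mapping[str, int], decimals: int = 1
) -> MemoryTable:
    """Tabulate class counts and percentage shares.

    Accepts either classified calls or a precomputed mtype -> count
    mapping (e.g. published class counts).
    """
    if isinstance(calls, Mapping):
        counts = {t: int(calls.get(t, 0)) for t in ALL_TYPES}
        counts["none"] = int(calls.get("none", 0))
    else:
        counts = {t: 0 for t in (*ALL_TYPES, "none")}
        for c in calls:
            counts[c.mtype] += 1
    total_memory = sum(counts[t] for t in MEMORY_TYPES)
    total_typed = sum(counts[t] for t in ALL_TYPES)
    fractions: dict[str, float] = {}
    for t in MEMORY_TYPES:
        fractions[t] = (round_half_up(100.0 * counts[t] / total_memory, decimals)
                        if total_memory else 0.0)
    for t in NON_MEMORY_TYPES + LATE_RESPONSE_TYPES:
        fractions[t] = (round_half_up(100.0 * counts[t] / total_typed, decimals)
                        if total_typed else 0.0)
    return MemoryTable(
        counts=counts,
        total_memory=total_memory,
        fractions=fractions,
        empty=(total_typed == 0 and counts["none"] == 0),
    )


def write_memory_table(calls: Sequence[MemoryCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.feature_id, c.s1, c.s2, c.mtype, c.category) for c in calls],
        columns=["feature_id", "s1", "s2", "mtype", "category"],
    )
    df.to_csv(path, sep="\t", index=False)
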