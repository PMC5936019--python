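"""Minimum-energy intermolecular RNA duplex between an mRNA and a lncRNA.

The model is a transparent simplification of RNAplex-style duplex folding:
two strands pair antiparallel (mRNA positions increase 5'->3' while the
paired lncRNA positions decrease), each Watson-Crick or GU wobble pair
contributes a negative energy (defaults GC = -3, AU = -2, GU = -1), and
consecutive pairs may be separated by a bulge or internal loop of at most
``max_loop`` unpaired bases *on each strand*, costing
``loop_open + loop_extend * (total unpaired bases)``.  Stacked pairs (no
unpaired bases between them) cost nothing beyond their pair energies.
Intramolecular structure, accessibility and Turner thermodynamics are out
of model.  Energies are in arbitrary units on this declared scale, not
kcal/mol.

``hybridize`` computes the global minimum by dynamic programming;
``brute_force_hybridize`` enumerates every legal pair set and serves as an
independent oracle on small inputs.  Reported intervals come from one
optimal duplex, ties broken toward the smallest (gene_start, lnc_start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "DuplexParams",
    "DuplexResult",
    "hybridize",
    "brute_force_hybridize",
    "scan_antisense_pairs",
    "read_fasta",
    "write_duplex_table",
]

_VALID = set("ACGU")
_DEFAULT_PAIRS = {"GC": -3.0, "AU": -2.0, "GU": -1.0}


@dataclass(frozen=True)
class DuplexParams:
    """Scoring parameters; pair energies are negative (stabilizing), loop
    penalties positive."""

    pair_scores: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PAIRS))
    loop_open: float = 4.0
    loop_extend: float = 1.0
    max_loop: int = 15

    def __post_init__(self) -> None:
        for k, v in self.pair_scores.items():
            if v >= 0:
                raise ValidationError(f"pair score {k} must be < 0")
        if self.loop_open <= 0 or self.loop_extend <= 0:
            raise ValidationError("loop penalties must be > 0")
        if self.max_loop < 1:
            raise ValidationError("max_loop must be >= 1")

    def score_table(self) -> dict[tuple[str, str], float]:
        """Symmetric base-pair energy lookup."""
        table: dict[tuple[str, str], float] = {}
        for pair, e in self.pair_scores.items():
            a, b = pair[0], pair[1]
            table[(a, b)] = e
            table[(b, a)] = e
        return table


@dataclass(frozen=True)
class DuplexResult:
    """Paired intervals (1-based, inclusive) and total energy.  Energy 0
    means no pair can form; interval sentinels are then 0."""

    gene_start: int
    gene_end: int
    lnc_start: int
    lnc_end: int
    energy: float

    def caption(self) -> str:
        """Figure-caption convention: 'g1, g2: l1, l2 (E)'."""
        return (f"{self.gene_start}, {self.gene_end}: "
                f"{self.lnc_start}, {self.lnc_end} ({self.energy:g})")


def _clean(seq: str, name: str) -> str:
    s = seq.upper().replace("T", "U")
    if not s:
        raise ValidationError(f"{name}: empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(f"{name}: invalid characters {sorted(bad)}")
    return s


_EMPTY = DuplexResult(0, 0, 0, 0, 0.0)


def hybridize(mrna_seq: str, lnc_seq: str, params: DuplexParams | None = None
              ) -> DuplexResult:
    """Minimum-energy duplex between an mRNA and a lncRNA (T auto-converted
    to U).  Returns the global minimum over all duplexes with >= 1 pair, or
    the zero-energy sentinel if no base pair can form."""
    params = params or DuplexParams()
    m = _clean(mrna_seq, "mrna_seq")
    l = _clean(lnc_seq, "lnc_seq")
    n1, n2 = len(m), len(l)
    table = params.score_table()
    L = params.max_loop
    open_, ext = params.loop_open, params.loop_extend

    # pair score matrix, 1-based in [1..n1] x [1..n2]; inf = cannot pair
    S = np.full((n1 + 1, n2 + 1), np.inf)
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            e = table.get((m[i - 1], l[j - 1]))
            if e is not None:
                S[i, j] = e
    if not np.isfinite(S).any():
        return _EMPTY

    # E[i, j]: best energy of a duplex whose LAST pair is (i, j)
    # (i runs 5'->3' on the mRNA, j 3'->5' on the lncRNA).
    E = np.full((n1 + 1, n2 + 1), np.inf)
    # G carries the affine-loop algebra: predecessor cost
    #   E[i',j'] + open + ext*((i - i' - 1) + (j' - j - 1))
    # = G[i',j'] + open + ext*((i - 1) - (j + 1))  with  G = E - ext*i + ext*j
    G = np.full((n1 + 1, n2 + 1), np.inf)
    for i in range(1, n1 + 1):
        lo = max(1, i - 1 - L)
        if lo <= i - 1:
            rowmin = G[lo:i, :].min(axis=0)  # min over admissible i'
        else:
            rowmin = np.full(n2 + 1, np.inf)
        # windowed min over j' in [j+1, j+1+L]
        shifted = np.full((L + 1, n2 + 1), np.inf)
        for d in range(L + 1):
            src = rowmin[1 + d:]
            if src.size:
                shifted[d, : src.size] = src
        loopmin = shifted.min(axis=0)
        js = np.arange(n2 + 1)
        best_prev = np.minimum(
            0.0, loopmin + open_ + ext * ((i - 1) - (js + 1)))
        # stacked predecessor (i-1, j+1): no loop cost
        stack = np.full(n2 + 1, np.inf)
        if i >= 2:
            stack[:n2] = E[i - 1, 1:]
        best_prev = np.minimum(best_prev, stack)
        E[i] = S[i] + best_prev
        G[i] = E[i] - ext * i + ext * js

    emin = E[1:, 1:].min()
    if not np.isfinite(emin) or emin >= 0:
        # at least one pair is possible and pair scores are < 0, so this
        # only happens when no pair exists (handled above); keep the guard
        return _EMPTY

    tol = 1e-9
    finals = np.argwhere(E <= emin + tol)
    candidates = []
    for i, j in finals:
        path = _traceback(int(i), int(j), E, S, params)
        gi = [p[0] for p in path]
        lj = [p[1] for p in path]
        candidates.append((min(gi), min(lj), max(gi), max(lj)))
    gene_start, lnc_start, gene_end, lnc_end = min(candidates)
    return DuplexResult(gene_start, gene_end, lnc_start, lnc_end, float(emin))


def _traceback(i: int, j: int, E: np.ndarray, S: np.ndarray,
               params: DuplexParams) -> list[tuple[int, int]]:
    """Recover one optimal duplex ending at pair (i, j) by re-deriving each
    step of the recurrence (predecessors scanned in ascending (i', j'))."""
    L, open_, ext = params.max_loop, params.loop_open, params.loop_extend
    tol = 1e-9
    path = [(i, j)]
    while True:
        rem = E[i, j] - S[i, j]
        if rem >= -tol:  # first pair of the duplex
            break
        found = False
        n2 = E.shape[1] - 1
        for ip in range(max(1, i - 1 - L), i):
            for jp in range(j + 1, min(n2, j + 1 + L) + 1):
                if not np.isfinite(E[ip, jp]):
                    continue
                gaps = (i - ip - 1) + (jp - j - 1)
                cost = 0.0 if gaps == 0 and ip == i - 1 and jp == j + 1 \
                    else open_ + ext * gaps
                if abs(E[ip, jp] + cost - rem) <= tol:
                    i, j = ip, jp
                    path.append((i, j))
                    found = True
                    break
            if found:
                break
        if not found:  # numerical safety net; should not happen
            break
    path.reverse()
    return path


def brute_force_hybridize(mrna_seq: str, lnc_seq: str,
                          params: DuplexParams | None = None) -> DuplexResult:
    """Exhaustive enumeration of every legal duplex pair set (independent
    oracle; guarded to len(mrna) * len(lnc) <= 200)."""
    params = params or DuplexParams()
    m = _clean(mrna_seq, "mrna_seq")
    l = _clean(lnc_seq, "lnc_seq")
    if len(m) * len(l) > 200:
        raise ValidationError(
            "brute_force_hybridize guard: len(mrna) * len(lnc) must be <= 200")
    table = params.score_table()
    L, open_, ext = params.max_loop, params.loop_open, params.loop_extend
    pairs = [(i, j, table[(m[i - 1], l[j - 1])])
             for i in range(1, len(m) + 1)
             for j in range(1, len(l) + 1)
             if (m[i - 1], l[j - 1]) in table]
    if not pairs:
        return _EMPTY

    best: list[tuple[float, int, int, int, int]] = []

    def extend(last_i: int, last_j: int, energy: float,
               i0: int, j0: int) -> None:
        best.append((energy, i0, last_j, last_i, j0))
        for i, j, s in pairs:
            if i <= last_i or j >= last_j:
                continue
            gi = i - last_i - 1
            gj = last_j - j - 1
            if gi > L or gj > L:
                continue
            cost = 0.0 if gi + gj == 0 else open_ + ext * (gi + gj)
            extend(i, j, energy + cost + s, i0, j0)

    for i, j, s in pairs:
        extend(i, j, s, i, j)

    energy, gene_start, lnc_start, gene_end, lnc_end = min(best)
    return DuplexResult(gene_start, gene_end, lnc_start, lnc_end, energy)


def count_optimal_duplexes(mrna_seq: str, lnc_seq: str,
                           params: DuplexParams | None = None,
                           tol: float = 1e-9) -> int:
    """Number of distinct pair sets achieving the brute-force optimum
    (used to identify tie-free instances)."""
    params = params or DuplexParams()
    m = _clean(mrna_seq, "mrna_seq")
    l = _clean(lnc_seq, "lnc_seq")
    if len(m) * len(l) > 200:
        raise ValidationError("count_optimal_duplexes: size guard exceeded")
    table = params.score_table()
    L, open_, ext = params.max_loop, params.loop_open, params.loop_extend
    pairs = [(i, j, table[(m[i - 1], l[j - 1])])
             for i in range(1, len(m) + 1)
             for j in range(1, len(l) + 1)
             if (m[i - 1], l[j - 1]) in table]
    if not pairs:
        return 0
    energies: list[float] = []

    def extend(last_i: int, last_j: int, energy: float) -> None:
        energies.append(energy)
        for i, j, s in pairs:
            if i <= last_i or j >= last_j:
                continue
            gi, gj = i - last_i - 1, last_j - j - 1
            if gi > L or gj > L:
                continue
            cost = 0.0 if gi + gj == 0 else open_ + ext * (gi + gj)
            extend(i, j, energy + cost + s)

    for i, j, s in pairs:
        extend(i, j, s)
    emin = min(energies)
    return sum(1 for e in energies if abs(e - emin) <= tol)


# ---------------------------------------------------------------------------
# batch scan over antisense annotation records

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def scan_antisense_pairs(
    records: Sequence,
    sequences: Mapping[str, str],
    params: DuplexParams | None = None,
) -> list[tuple[str, str, DuplexResult]]:
    """Hybridize each antisense (lnc, gene) annotation record.  Results are
    ordered by (lnc_id, gene_id); a missing sequence is an error listing
    the offending IDs."""
    params = params or DuplexParams()
    antisense = sorted(
        ((r.lnc_id, r.gene_id) for r in records if r.relation == "antisense"))
    missing = sorted({fid for pair in antisense for fid in pair
                      if fid not in sequences})
    if missing:
        raise ValidationError(f"sequences missing for: {missing}")
    return [
        (lnc_id, gene_id,
         hybridize(sequences[gene_id], sequences[lnc_id], params))
        for lnc_id, gene_id in antisense
    ]


def write_duplex_table(
    results: Sequence[tuple[str, str, DuplexResult]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (lnc, gene, r.gene_start, r.gene_end, r.lnc_start, r.lnc_end,
             r.energy, r.caption())
            for lnc, gene, r in results
        ],
        columns=["lnc_id", "gene_id", "gene_start", "gene_end",
                 "lnc_start", "lnc_end", "energy", "caption"],
    )
    df.to_csv(path, sep="\t", index=False)
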