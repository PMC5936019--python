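"""Dataset-level accounting: expressed fractions, length and chromosome
distributions, set intersections, and qPCR relative quantification."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .core import ExpressionMatrix, GenomicFeature, ValidationError
from ._util import percentage, round_half_up

__all__ = [
    "ExpressionStats",
    "expression_stats",
    "LengthDistribution",
    "length_distribution",
    "chromosome_distribution",
    "venn_counts",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class ExpressionStats:
    """Expressed-feature accounting for one feature kind.

    ``pct_expressed`` is relative to the predicted total (two decimals by
    default, the headline precision); ``pct_expressed_all`` is the share
    of expressed features detected in every sample (one decimal).
    """

    n_predicted: int
    n_expressed: int
    n_expressed_all_samples: int
    pct_expressed: float
    pct_expressed_all: float


def expression_stats(
    matrix: ExpressionMatrix,
    feature_kind: str = "lncRNA",
    kinds: Mapping[str, str] | None = None,
    expressed_min_fpkm: float = 0.0,
    decimals: tuple[int, int] = (2, 1),
) -> ExpressionStats:
    """Count features of one kind that are expressed (FPKM >
    ``expressed_min_fpkm`` in at least one sample) and expressed in every
    sample.

    ``kinds`` maps feature_id -> kind; if omitted, all rows of the matrix
    are taken to be of ``feature_kind``.
    """
    if feature_kind not in ("gene", "lncRNA"):
        raise ValidationError(f"unknown feature kind {feature_kind!r}")
    if kinds is None:
        sub = matrix.values
    else:
        keep = [f for f in matrix.features if kinds.get(f) == feature_kind]
        sub = matrix.values.loc[keep]
    arr = sub.to_numpy(dtype=float)
    n_predicted = arr.shape[0]
    expressed = (arr > expressed_min_fpkm).any(axis=1)
    expressed_all = (arr > expressed_min_fpkm).all(axis=1)
    n_expressed = int(expressed.sum())
    n_all = int(expressed_all.sum())
    return ExpressionStats(
        n_predicted=n_predicted,
        n_expressed=n_expressed,
        n_expressed_all_samples=n_all,
        pct_expressed=(percentage(n_expressed, n_predicted, decimals[0])
                       if n_predicted else 0.0),
        pct_expressed_all=(percentage(n_all, n_expressed, decimals[1])
                           if n_expressed else 0.0),
    )


@dataclass(frozen=True)
class LengthDistribution:
    """Histogram of feature lengths with [k*bin, (k+1)*bin) intervals."""

    bin_width: int
    counts: Mapping[int, int]  # bin start -> count
    lengths: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.lengths)

    def fraction_below(self, threshold: int, decimals: int = 1) -> float:
        """Percentage of features strictly shorter than ``threshold`` bp."""
        if self.n == 0:
            return 0.0
        below = sum(1 for x in self.lengths if x < threshold)
        return percentage(below, self.n, decimals)


def length_distribution(
    features: Iterable[GenomicFeature], bin_width: int = 200
) -> LengthDistribution:
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    lengths = tuple(f.length for f in features)
    counts = Counter((x // bin_width) * bin_width for x in lengths)
    return LengthDistribution(
        bin_width=bin_width,
        counts=dict(sorted(counts.items())),
        lengths=lengths,
    )


def chromosome_distribution(
    features: Iterable[GenomicFeature],
) -> dict[str, int]:
    """Feature counts per chromosome, sorted by name (case-sensitive names
    kept distinct)."""
    counts = Counter(f.chrom for f in features)
    return dict(sorted(counts.items()))


def venn_counts(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable]
) -> tuple[int, int, int]:
    """Two-set partition counts (only_a, both, only_b)."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def delta_delta_ct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-ddCT with
    ddCT = (CT_target,treat - CT_ref,treat) - (CT_target,ctrl - CT_ref,ctrl).

    The reference gene plays the role of the internal control (the study's
    reference was the switchgrass elongation factor PveEF-1a).
    """
    for v in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValidationError("CT values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
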