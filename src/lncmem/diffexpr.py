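"""Per-contrast differential expression and three-way symbol calling.

The calling rule is the study's own computation: a feature is upregulated
("+") in a contrast when log2 fold change >= 1 and q <= 0.05, downregulated
("-") when log2 fold change <= -1 and q <= 0.05, and unchanged ("=")
otherwise.  Both thresholds are inclusive and configurable.

Significance testing is pluggable.  The default internal test is an
empirical-Bayes moderated t (Smyth 2004): per-feature log2-scale variances
are shrunk toward a pooled prior fitted across all features of the
contrast, which restores power at the n=2-replicates-per-treatment design
this pipeline targets.  A plain per-feature Welch t is available, and a
supplied-q mode accepts externally computed q-values (from any DE engine)
and applies only the thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ValidationError

__all__ = [
    "DEThresholds",
    "DERecord",
    "compute_log2fc",
    "test_feature",
    "benjamini_hochberg",
    "call_symbol",
    "run_contrast",
    "write_de_table",
    "read_de_table",
    "read_supplied_q",
]

SYMBOLS = ("+", "-", "=")


@dataclass(frozen=True)
class DEThresholds:
    """Calling thresholds: |log2FC| >= ``min_abs_log2fc`` and
    q <= ``max_q``, both inclusive.  ``pseudocount`` (FPKM) bounds fold
    changes on zero-expression features."""

    min_abs_log2fc: float = 1.0
    max_q: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_q <= 1):
            raise ValidationError("max_q must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    contrast: tuple[str, str]
    log2fc: float
    p: float
    q: float
    symbol: str


def compute_log2fc(
    treat_values: Sequence[float],
    ctrl_values: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """log2((mean(treat) + c) / (mean(ctrl) + c)); finite for all valid
    FPKM inputs, 0 when the two means are equal (any pseudocount)."""
    treat = np.asarray(treat_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if treat.size == 0 or ctrl.size == 0:
        raise ValidationError("compute_log2fc: empty value list")
    if (treat < 0).any() or (ctrl < 0).any():
        raise ValidationError("compute_log2fc: FPKM values must be >= 0")
    if pseudocount <= 0:
        raise ValidationError("compute_log2fc: pseudocount must be > 0")
    return float(np.log2((treat.mean() + pseudocount) / (ctrl.mean() + pseudocount)))


def test_feature(
    treat_values: Sequence[float],
    ctrl_values: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """Two-sided Welch t on log2(FPKM + pseudocount) for one feature.

    Degenerate variance (all replicate values equal in both groups) yields
    p = 1 when the group means agree — no evidence of change — and p = 0
    when they differ exactly.
    """
    treat = np.asarray(treat_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if treat.size < 2 or ctrl.size < 2:
        raise ValidationError(
            "test_feature needs >= 2 replicates per group; with fewer, "
            "use supplied-q mode"
        )
    lt = np.log2(treat + pseudocount)
    lc = np.log2(ctrl + pseudocount)
    if lt.std() == 0 and lc.std() == 0:
        return 1.0 if lt.mean() == lc.mean() else 0.0
    p = stats.ttest_ind(lt, lc, equal_var=False).pvalue
    return float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini–Hochberg q-values in input order (monotonicity
    enforced; q >= p elementwise, q <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_symbol(log2fc: float, q: float, thresholds: DEThresholds) -> str:
    """Three-way symbol: '+', '-' or '=' (pure function of log2fc, q and
    the thresholds; the three cases are exhaustive and exclusive)."""
    if q <= thresholds.max_q:
        if log2fc >= thresholds.min_abs_log2fc:
            return "+"
        if log2fc <= -thresholds.min_abs_log2fc:
            return "-"
    return "="


# ---------------------------------------------------------------------------
# moderated t (empirical Bayes, Smyth 2004)

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration, limma's scheme)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit a scaled F prior to observed variances: returns (d0, s0_sq).

    Method-of-moments on log variances; d0 = inf means a common variance.
    Zero variances are handled by flooring at a tiny positive value.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    if e.size < 2:
        return np.inf, float(np.exp(ebar))
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_ttest(
    treat: np.ndarray, ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature moderated two-sample t on log-scale data.

    ``treat`` and ``ctrl`` are features x replicates arrays (already on the
    log2 scale).  Residual variances are shrunk toward the empirical-Bayes
    prior fitted across features; the t statistic uses the shrunk variance
    with df = d0 + d_residual.  Returns (t, p) arrays.

    Features where every replicate in both groups is identical and the
    means agree get p = 1 (degenerate-variance rule).
    """
    treat = np.asarray(treat, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    n1, n2 = treat.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("moderated_ttest needs >= 2 replicates per group")
    df_resid = n1 + n2 - 2
    delta = treat.mean(axis=1) - ctrl.mean(axis=1)
    ss = treat.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    if np.all(s2 < 1e-12):
        # noise-free data: no variance information anywhere
        p = np.where(delta == 0.0, 1.0, 0.0)
        with np.errstate(invalid="ignore"):
            t = np.where(delta == 0.0, 0.0, np.inf * np.sign(delta))
        return t, p
    d0, s0_sq = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    degenerate = (se == 0) & (delta == 0)
    p = np.where(degenerate, 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(se == 0,
                     np.where(delta == 0, 0.0, np.sign(delta) * np.inf), t)
    return t, np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# contrast runner

def run_contrast(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    thresholds: DEThresholds | None = None,
    supplied_q: pd.DataFrame | None = None,
    method: str = "moderated",
) -> list[DERecord]:
    """Compute one DERecord per feature for a (numerator, denominator)
    treatment contrast, e.g. ("D1", "C1") or ("D2", "D1").

    If ``supplied_q`` is given (indexed by feature_id with column ``q`` and
    optionally ``log2fc``), it overrides internal testing; otherwise
    ``method`` selects "moderated" (default) or "welch".  BH correction is
    applied across all features within the contrast.
    """
    thresholds = thresholds or DEThresholds()
    num, den = contrast
    treat = matrix.treatment_values(num).to_numpy()
    ctrl = matrix.treatment_values(den).to_numpy()
    features = matrix.features
    c = thresholds.pseudocount

    lfc = np.log2(treat.mean(axis=1) + c) - np.log2(ctrl.mean(axis=1) + c)

    if supplied_q is not None:
        missing = [f for f in features if f not in supplied_q.index]
        if missing:
            raise ValidationError(
                f"supplied_q table missing {len(missing)} features "
                f"(first: {missing[:3]})"
            )
        q = supplied_q.loc[features, "q"].to_numpy(dtype=float)
        p = q.copy()
        if "log2fc" in supplied_q.columns:
            ext = supplied_q.loc[features, "log2fc"]
            lfc = np.where(ext.notna(), ext.to_numpy(dtype=float), lfc)
    else:
        lt = np.log2(treat + c)
        lc = np.log2(ctrl + c)
        if method == "moderated":
            _, p = moderated_ttest(lt, lc)
        elif method == "welch":
            if treat.shape[1] < 2 or ctrl.shape[1] < 2:
                raise ValidationError(
                    "internal testing needs >= 2 replicates per group; "
                    "use supplied-q mode"
                )
            p = np.array([
                test_feature(treat[i], ctrl[i], c) for i in range(len(features))
            ])
        else:
            raise ValidationError(f"unknown test method {method!r}")
        q = benjamini_hochberg(p)

    records = [
        DERecord(
            feature_id=fid,
            contrast=(num, den),
            log2fc=float(lfc[i]),
            p=float(p[i]),
            q=float(q[i]),
            symbol=call_symbol(float(lfc[i]), float(q[i]), thresholds),
        )
        for i, fid in enumerate(features)
    ]
    records.sort(key=lambda r: r.feature_id)
    return records


# ---------------------------------------------------------------------------
# TSV interfaces

def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "contrast": [f"{r.contrast[0]}/{r.contrast[1]}" for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "symbol": [r.symbol for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "symbol": str})
    records = []
    for row in df.itertuples(index=False):
        num, den = row.contrast.split("/")
        records.append(
            DERecord(row.feature_id, (num, den), float(row.log2fc),
                     float(row.p), float(row.q), row.symbol)
        )
    return records


def read_supplied_q(path: str | Path) -> pd.DataFrame:
    """Read an external q-value table: columns feature_id, q[, log2fc]."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    if "feature_id" not in df.columns or "q" not in df.columns:
        raise ValidationError("supplied-q table needs columns feature_id, q")
    return df.set_index("feature_id")
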