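"""Synthetic fixture generator with planted ground truth.

Emulates the data regime of a repeated-dehydration lncRNA study: tens of
chromosomes carrying gene and lncRNA loci, lncRNA lengths >= 200 nt and
skewed short, planted antisense/upstream/downstream relations within the
annotation window, planted memory types realized as +/- ``effect_log2fc``
shifts of treatment means at the C1->D1 and D1->D2 steps (R1 returns to
baseline), and multiplicative log-normal replicate noise on FPKM.

The geometry places one gene per 12-kb slot with wide margins, so every
planted relation is recovered exactly by the annotator and no accidental
relation can arise.  Transcript sequences are random RNA; each antisense
pair carries an embedded reverse-complementary window so its duplex
energy is strictly negative.

Everything is driven by one integer seed and is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicFeature,
    SampleInfo,
    ValidationError,
    write_annotation,
    write_expression,
)
from .diffexpr import DEThresholds, run_contrast
from .memory import ALL_TYPES, call_memory

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate",
           "write_fixture", "mtype_recovery"]

_RELATIONS = ("antisense", "upstream", "downstream", "unlinked")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

_SLOT = 12_000       # one gene per slot
_GENE_OFFSET = 4_500  # gene start within its slot; leaves room for flanks


def _default_relation_mix() -> dict[str, float]:
    # ~28% of lncRNAs annotated, antisense slightly ahead of flanking,
    # matching the observed annotation fractions
    return {"antisense": 0.13, "upstream": 0.075, "downstream": 0.075,
            "unlinked": 0.72}


def _default_memory_mix() -> dict[str, float]:
    # [+/-] dominates the memory classes, as observed; half the lncRNAs
    # are never differentially expressed
    return {"[+/+]": 0.03, "[+/-]": 0.08, "[-/+]": 0.05, "[-/-]": 0.03,
            "[+/=]": 0.08, "[-/=]": 0.08, "[=/+]": 0.08, "[=/-]": 0.07,
            "none": 0.50}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 18
    chrom_len: int = 300_000
    n_genes: int = 120
    n_lncs: int = 200
    relation_mix: Mapping[str, float] = field(
        default_factory=_default_relation_mix)
    memory_mix: Mapping[str, float] = field(default_factory=_default_memory_mix)
    effect_log2fc: float = 2.0
    rep_sd: float = 0.2
    base_fpkm_log_mean: float = 4.0   # log2 scale
    base_fpkm_log_sd: float = 1.5     # log2 scale
    n_reps: int = 2
    window: int = 2000
    silent_frac_lnc: float = 0.02     # never-expressed share (none-type only)
    silent_frac_gene: float = 0.10

    def __post_init__(self) -> None:
        if abs(sum(self.relation_mix.values()) - 1) > 1e-9:
            raise ValidationError("relation_mix proportions must sum to 1")
        if set(self.relation_mix) != set(_RELATIONS):
            raise ValidationError(f"relation_mix keys must be {_RELATIONS}")
        if abs(sum(self.memory_mix.values()) - 1) > 1e-9:
            raise ValidationError("memory_mix proportions must sum to 1")
        if set(self.memory_mix) != set((*ALL_TYPES, "none")):
            raise ValidationError("memory_mix keys must be the 8 types + none")
        if self.effect_log2fc < 1.0:
            raise ValidationError(
                "effect_log2fc must be >= the 1.0 calling threshold so "
                "planted effects are detectable")
        if self.rep_sd < 0 or self.n_reps < 1:
            raise ValidationError("rep_sd >= 0 and n_reps >= 1 required")


@dataclass
class TruthTable:
    """Planted truth: one row per lncRNA in ``relations`` (partner gene,
    geometry and memory type) and per-feature planted mean FPKM per
    treatment in ``means``."""

    relations: pd.DataFrame
    means: pd.DataFrame  # index feature_id, columns C1/D1/R1/D2

    def supplied_q(self, contrast: tuple[str, str]) -> pd.DataFrame:
        """Ground-truth q table for one contrast: q = 0 where an effect
        was planted at that step, q = 1 elsewhere."""
        step = {("D1", "C1"): "s1", ("D2", "D1"): "s2"}.get(tuple(contrast))
        if step is None:
            raise ValidationError(f"no planted step for contrast {contrast}")
        sym = self.relations.set_index("lnc_id")[step]
        q = pd.Series(1.0, index=self.means.index, name="q")
        planted = sym.index[sym != "="]
        q.loc[planted] = 0.0
        return q.to_frame()


@dataclass
class SimResult:
    config: SimConfig
    features: list[GenomicFeature]
    sequences: dict[str, str]
    matrix: ExpressionMatrix
    truth: TruthTable

    @property
    def genes(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == "gene"]

    @property
    def lncs(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == "lncRNA"]


def _chrom_names(n: int) -> list[str]:
    return [f"Chr{i // 2 + 1:02d}{'ab'[i % 2]}" for i in range(n)]


def _counts_from_mix(mix: Mapping[str, float], n: int,
                     order: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder apportionment so class counts sum exactly to n."""
    raw = {k: mix[k] * n for k in order}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(order, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


def simulate(config: SimConfig) -> SimResult:
    """Generate a fully labelled fixture; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config.n_chroms)
    slots_per_chrom = config.chrom_len // _SLOT
    all_slots = [(c, s) for c in chroms for s in range(slots_per_chrom)]
    if config.n_genes + 1 > len(all_slots):
        raise ValidationError(
            f"infeasible geometry: {config.n_genes} genes need more than the "
            f"{len(all_slots)} available {_SLOT}-bp slots")

    slot_idx = rng.permutation(len(all_slots))
    gene_slots = [all_slots[i] for i in slot_idx[: config.n_genes]]
    free_slots = [all_slots[i] for i in slot_idx[config.n_genes:]]

    genes: list[GenomicFeature] = []
    for k, (chrom, slot) in enumerate(gene_slots):
        start = slot * _SLOT + _GENE_OFFSET
        length = int(rng.integers(1000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GenomicFeature(
            f"gene_{k:05d}", chrom, start, start + length - 1, strand, "gene"))

    rel_counts = _counts_from_mix(config.relation_mix, config.n_lncs, _RELATIONS)
    relations = rng.permutation(
        [r for r, c in rel_counts.items() for _ in range(c)])
    mem_counts = _counts_from_mix(
        config.memory_mix, config.n_lncs, (*ALL_TYPES, "none"))
    mtypes = rng.permutation(
        [t for t, c in mem_counts.items() for _ in range(c)])

    lncs: list[GenomicFeature] = []
    truth_rows: list[dict] = []
    free_cursor = 0
    for k in range(config.n_lncs):
        rel = str(relations[k])
        mtype = str(mtypes[k])
        length = 200 + int(rng.exponential(300.0))
        length = min(length, 2000)
        lnc_id = f"lnc_{k:05d}"
        partner = None
        distance = 0
        overlap_len = 0
        if rel == "unlinked":
            chrom, slot = free_slots[free_cursor % len(free_slots)]
            free_cursor += 1
            start = slot * _SLOT + _GENE_OFFSET + int(rng.integers(0, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            g = genes[int(rng.integers(0, len(genes)))]
            partner = g
            chrom = g.chrom
            if rel == "antisense":
                length = min(length, g.length)  # placed fully inside the gene
                start = g.start + int(rng.integers(0, g.length - length + 1))
                strand = "-" if g.strand == "+" else "+"
                overlap_len = length
            else:
                distance = int(rng.integers(1, config.window + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                # place on the gene's 5' side for upstream, 3' for downstream
                left_side = (g.strand == "+") == (rel == "upstream")
                if left_side:
                    end = g.start - distance
                    start = end - length + 1
                else:
                    start = g.end + distance
        lncs.append(GenomicFeature(
            lnc_id, chrom, start, start + length - 1, strand, "lncRNA"))
        s1, s2 = ("=", "=") if mtype == "none" else (mtype[1], mtype[3])
        truth_rows.append({
            "lnc_id": lnc_id,
            "relation": rel,
            "gene_id": partner.feature_id if partner else "",
            "distance": distance,
            "overlap_len": overlap_len,
            "mtype": mtype,
            "s1": s1,
            "s2": s2,
        })

    # ---- sequences -------------------------------------------------------
    sequences: dict[str, str] = {}
    for g in genes:
        sequences[g.feature_id] = _random_rna(rng, int(rng.integers(150, 401)))
    for lnc, row in zip(lncs, truth_rows):
        seq = _random_rna(rng, max(200, min(lnc.length, 400)))
        if row["relation"] == "antisense":
            gene_seq = sequences[row["gene_id"]]
            w = int(rng.integers(40, 81))
            w = min(w, len(gene_seq), len(seq))
            gpos = int(rng.integers(0, len(gene_seq) - w + 1))
            window = gene_seq[gpos:gpos + w]
            rc = window.translate(_COMPLEMENT)[::-1]
            lpos = int(rng.integers(0, len(seq) - w + 1))
            seq = seq[:lpos] + rc + seq[lpos + w:]
        sequences[lnc.feature_id] = seq

    # ---- expression ------------------------------------------------------
    eff = config.effect_log2fc
    step = {"+": eff, "-": -eff, "=": 0.0}
    feature_ids = [f.feature_id for f in genes] + [f.feature_id for f in lncs]
    base = 2.0 ** rng.normal(config.base_fpkm_log_mean,
                             config.base_fpkm_log_sd, len(feature_ids))
    # planted-effect lncRNAs draw their baseline from the log-normal
    # truncated below: under the 1-FPKM log2FC pseudocount, the hardest
    # case (a second consecutive down-step, b*2^-e -> b*2^-2e) only shows
    # |log2FC| >= 1 when b >= 2^e / (1 - 2^(1-e)); planted effects are by
    # construction at or above the calling threshold
    from scipy import stats as _stats

    denom = 1.0 - 2.0 ** (1.0 - eff)
    b_min = (2.0 ** eff) / denom if denom > 1e-9 else 1024.0
    lo_z = (np.log2(b_min) - config.base_fpkm_log_mean) / config.base_fpkm_log_sd
    planted_idx = [len(genes) + i for i, r in enumerate(truth_rows)
                   if r["mtype"] != "none"]
    if planted_idx:
        u = rng.random(len(planted_idx))
        z = _stats.norm.ppf(_stats.norm.cdf(lo_z) * (1 - u) + u)
        base[planted_idx] = 2.0 ** (config.base_fpkm_log_mean
                                    + config.base_fpkm_log_sd * z)
    means = pd.DataFrame(
        {"C1": base, "D1": base, "R1": base, "D2": base},
        index=pd.Index(feature_ids, name="feature_id"), dtype=float)
    for row, b in zip(truth_rows, base[len(genes):]):
        d1 = b * 2.0 ** step[row["s1"]]
        means.loc[row["lnc_id"], "D1"] = d1
        means.loc[row["lnc_id"], "D2"] = d1 * 2.0 ** step[row["s2"]]

    # silent features: never expressed (genes, and none-type lncRNAs only,
    # so planted effects stay observable)
    n_silent_genes = int(round(config.silent_frac_gene * len(genes)))
    silent = list(rng.choice([g.feature_id for g in genes],
                             size=n_silent_genes, replace=False))
    none_lncs = [r["lnc_id"] for r in truth_rows if r["mtype"] == "none"]
    n_silent_lncs = min(int(round(config.silent_frac_lnc * len(lncs))),
                        len(none_lncs))
    silent += list(rng.choice(none_lncs, size=n_silent_lncs, replace=False))
    means.loc[silent, :] = 0.0

    samples = [
        SampleInfo(f"{t}_{r}", t, r)
        for t in ("C1", "D1", "R1", "D2")
        for r in range(1, config.n_reps + 1)
    ]
    noise = rng.normal(0.0, config.rep_sd,
                       (len(feature_ids), len(samples)))
    values = np.empty((len(feature_ids), len(samples)))
    for si, s in enumerate(samples):
        values[:, si] = means[s.treatment].to_numpy() * 2.0 ** noise[:, si]
    matrix = ExpressionMatrix(
        samples=samples,
        values=pd.DataFrame(values, index=means.index,
                            columns=[s.sample_id for s in samples]),
    )

    truth = TruthTable(relations=pd.DataFrame(truth_rows), means=means)
    return SimResult(config=config, features=genes + lncs,
                     sequences=sequences, matrix=matrix, truth=truth)


# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(sim: SimResult, out_dir: str | Path) -> dict:
    """Write the fixture as standard files plus a manifest with the config
    echo and per-file sha256 checksums.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_annotation(sim.features, out / "features.gff3")
    with open(out / "sequences.fasta", "wt", encoding="utf-8") as fh:
        for fid in sorted(sim.sequences):
            fh.write(f">{fid}\n{sim.sequences[fid]}\n")
    write_expression(sim.matrix, out / "expression.tsv")
    sim.truth.relations.to_csv(out / "truth_relations.tsv", sep="\t",
                               index=False)
    sim.truth.means.to_csv(out / "truth_means.tsv", sep="\t")
    for contrast, name in ((("D1", "C1"), "truth_q_D1C1.tsv"),
                           (("D2", "D1"), "truth_q_D2D1.tsv")):
        sim.truth.supplied_q(contrast).to_csv(out / name, sep="\t")

    files = ["features.gff3", "sequences.fasta", "expression.tsv",
             "truth_relations.tsv", "truth_means.tsv",
             "truth_q_D1C1.tsv", "truth_q_D2D1.tsv"]
    manifest = {
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(sim.config).items()},
        "checksums": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def mtype_recovery(
    sim: SimResult,
    thresholds: DEThresholds | None = None,
    use_truth_q: bool = False,
    method: str = "moderated",
) -> float:
    """Run the DE + memory pipeline on a simulation and return the fraction
    of lncRNAs whose called memory type equals the planted one.

    With ``use_truth_q`` the generator's ground-truth q tables stand in
    for an external DE engine (supplied-q mode); otherwise the internal
    test is used.
    """
    thresholds = thresholds or DEThresholds()
    de = {}
    for contrast in (("D1", "C1"), ("D2", "D1")):
        sq = sim.truth.supplied_q(contrast) if use_truth_q else None
        de[contrast] = run_contrast(sim.matrix, contrast, thresholds,
                                    supplied_q=sq, method=method)
    lnc_ids = {f.feature_id for f in sim.lncs}
    calls = call_memory(de[("D1", "C1")], de[("D2", "D1")])
    called = {c.feature_id: c.mtype for c in calls if c.feature_id in lnc_ids}
    planted = sim.truth.relations.set_index("lnc_id")["mtype"]
    hits = sum(1 for fid, t in planted.items() if called[fid] == t)
    return hits / len(planted)
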