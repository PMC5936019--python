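"""Positional lncRNA-to-gene annotation.

A lncRNA is assigned to target genes either as an *antisense* partner
(same chromosome, opposite strand, >= 1 bp overlap — the positional
precondition for complementary base-pairing with the mRNA) or as a
*flanking* partner lying within a window (default 2000 bp) upstream or
downstream of a gene.  Upstream/downstream is relative to the gene's
strand: the upstream side is the 5' promoter side.  The lncRNA's own
strand is ignored for flanking classification.

Distances use the coordinate-difference convention: the gene's 5' (or 3')
boundary coordinate minus the nearest lncRNA boundary, in absolute bp
(gap + 1 under a between-bases count).  A gene [5000, 8000]+ with a lncRNA
ending at 3771 gives distance 5000 - 3771 = 1229.  The window test is
inclusive: distance <= window annotates.  ``distance_convention="gap"``
switches to pure gap counting.

For class accounting each annotated lncRNA is assigned to exactly one
class with precedence antisense > flanking, so the per-class counts are
disjoint and sum to the annotated total.  Same-strand overlap is recorded
as ``overlapping_sense`` but belongs to neither class.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GenomicFeature, ValidationError

__all__ = [
    "AnnotationRecord",
    "AnnotationSummary",
    "find_antisense",
    "find_flanking",
    "annotate_all",
    "write_annotation_records",
    "read_annotation_records",
]

RELATIONS = ("antisense", "upstream", "downstream", "overlapping_sense")


@dataclass(frozen=True)
class AnnotationRecord:
    """One lncRNA -> gene relation.

    ``distance`` is 0 for overlapping relations; ``overlap_len`` is 0 for
    flanking relations.
    """

    lnc_id: str
    gene_id: str
    relation: str
    distance: int
    overlap_len: int

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")
        if self.relation in ("antisense", "overlapping_sense"):
            if self.overlap_len < 1 or self.distance != 0:
                raise ValidationError(
                    f"{self.lnc_id}->{self.gene_id}: overlapping relation "
                    "requires overlap_len >= 1 and distance = 0"
                )
        else:
            if self.distance < 1 or self.overlap_len != 0:
                raise ValidationError(
                    f"{self.lnc_id}->{self.gene_id}: flanking relation "
                    "requires distance >= 1 and overlap_len = 0"
                )


@dataclass(frozen=True)
class AnnotationSummary:
    """Class accounting: unique lncRNAs and unique genes per class.

    ``n_annotated_lnc = n_antisense_lnc + n_flank_lnc`` (classes are
    disjoint after precedence); ``n_target_genes`` is the sum of the two
    per-class unique gene counts (a gene targeted both ways counts in
    each class).
    """

    n_antisense_lnc: int
    n_flank_lnc: int
    n_antisense_genes: int
    n_flank_genes: int

    @property
    def n_annotated_lnc(self) -> int:
        return self.n_antisense_lnc + self.n_flank_lnc

    @property
    def n_target_genes(self) -> int:
        return self.n_antisense_genes + self.n_flank_genes


def _overlap(a: GenomicFeature, b: GenomicFeature) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def find_antisense(
    lnc: GenomicFeature, genes: Sequence[GenomicFeature]
) -> list[AnnotationRecord]:
    """All genes overlapping ``lnc`` by >= 1 bp on the opposite strand of
    the same chromosome.  Adjacency is not overlap."""
    out = []
    for g in genes:
        if g.chrom != lnc.chrom or g.strand == lnc.strand:
            continue
        ov = _overlap(lnc, g)
        if ov >= 1:
            out.append(AnnotationRecord(lnc.feature_id, g.feature_id,
                                        "antisense", 0, ov))
    return out


def _flank_record(
    lnc: GenomicFeature,
    g: GenomicFeature,
    window: int,
    distance_convention: str,
) -> AnnotationRecord | None:
    if g.chrom != lnc.chrom or _overlap(lnc, g) >= 1:
        return None
    if lnc.end < g.start:  # lncRNA on the left
        gap = g.start - lnc.end - 1
        side_is_5prime = g.strand == "+"
    else:  # lncRNA on the right
        gap = lnc.start - g.end - 1
        side_is_5prime = g.strand == "-"
    distance = gap if distance_convention == "gap" else gap + 1
    if distance < 1 or distance > window:
        return None
    relation = "upstream" if side_is_5prime else "downstream"
    return AnnotationRecord(lnc.feature_id, g.feature_id, relation, distance, 0)


def find_flanking(
    lnc: GenomicFeature,
    genes: Sequence[GenomicFeature],
    window: int = 2000,
    distance_convention: str = "coordinate",
) -> list[AnnotationRecord]:
    """All non-overlapping genes of the same chromosome within ``window``
    bp of ``lnc``, labelled upstream/downstream relative to gene strand."""
    if distance_convention not in ("coordinate", "gap"):
        raise ValidationError(
            f"distance_convention must be 'coordinate' or 'gap', "
            f"got {distance_convention!r}"
        )
    out = []
    for g in genes:
        rec = _flank_record(lnc, g, window, distance_convention)
        if rec is not None:
            out.append(rec)
    return out


def annotate_all(
    lncs: Sequence[GenomicFeature],
    genes: Sequence[GenomicFeature],
    window: int = 2000,
    distance_convention: str = "coordinate",
) -> tuple[list[AnnotationRecord], AnnotationSummary]:
    """Annotate every lncRNA against every gene.

    Uses per-chromosome sorted gene lists with a bisect window so only
    nearby genes are examined.  Returns all retained pair records
    (antisense, flanking and overlapping_sense) sorted by
    (lnc_id, gene_id), plus the class summary with antisense > flanking
    precedence applied per lncRNA.
    """
    for coll, name in ((lncs, "lncRNA"), (genes, "gene")):
        ids = [f.feature_id for f in coll]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate {name} IDs")

    by_chrom: dict[str, list[GenomicFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: (g.start, g.end, g.feature_id))
        starts[chrom] = [g.start for g in gl]
        max_len[chrom] = max(g.length for g in gl)

    records: list[AnnotationRecord] = []
    antisense_lncs: set[str] = set()
    flank_lncs: set[str] = set()
    antisense_genes: set[str] = set()
    flank_genes_by_lnc: dict[str, set[str]] = {}

    for lnc in lncs:
        gl = by_chrom.get(lnc.chrom)
        if not gl:
            continue
        # any gene interacting with lnc starts within this coordinate range
        lo = bisect_left(starts[lnc.chrom], lnc.start - window - max_len[lnc.chrom])
        hi = bisect_right(starts[lnc.chrom], lnc.end + window)
        has_antisense = False
        flank_partners: set[str] = set()
        for g in gl[lo:hi]:
            if _overlap(lnc, g) >= 1:
                if g.strand != lnc.strand:
                    records.append(AnnotationRecord(
                        lnc.feature_id, g.feature_id, "antisense", 0,
                        _overlap(lnc, g)))
                    has_antisense = True
                    antisense_genes.add(g.feature_id)
                else:
                    records.append(AnnotationRecord(
                        lnc.feature_id, g.feature_id, "overlapping_sense", 0,
                        _overlap(lnc, g)))
            else:
                rec = _flank_record(lnc, g, window, distance_convention)
                if rec is not None:
                    records.append(rec)
                    flank_partners.add(g.feature_id)
        if has_antisense:
            antisense_lncs.add(lnc.feature_id)
        elif flank_partners:
            flank_lncs.add(lnc.feature_id)
            flank_genes_by_lnc[lnc.feature_id] = flank_partners

    flank_genes = set().union(*flank_genes_by_lnc.values()) if flank_genes_by_lnc else set()
    summary = AnnotationSummary(
        n_antisense_lnc=len(antisense_lncs),
        n_flank_lnc=len(flank_lncs),
        n_antisense_genes=len(antisense_genes),
        n_flank_genes=len(flank_genes),
    )
    records.sort(key=lambda r: (r.lnc_id, r.gene_id, r.relation))
    return records, summary


def write_annotation_records(
    records: Iterable[AnnotationRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(r.lnc_id, r.gene_id, r.relation, r.distance, r.overlap_len)
         for r in records],
        columns=["lnc_id", "gene_id", "relation", "distance", "overlap_len"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_records(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "gene_id": str})
    return [
        AnnotationRecord(r.lnc_id, r.gene_id, r.relation,
                         int(r.distance), int(r.overlap_len))
        for r in df.itertuples(index=False)
    ]
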