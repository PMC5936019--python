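"""Antisense/flanking annotation, checked against an independent
all-pairs oracle written from the rule definitions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncmem.annotator import (
    AnnotationRecord,
    annotate_all,
    find_antisense,
    find_flanking,
)
from lncmem.core import GenomicFeature, ValidationError


def F(fid, chrom, start, end, strand, kind):
    return GenomicFeature(fid, chrom, start, end, strand, kind)


# ---------------------------------------------------------------------------
# independent oracle: literal all-pairs restatement of the rules

def oracle_pairs(lncs, genes, window=2000):
    """(lnc_id, gene_id, relation, distance, overlap) for every pair, by
    direct interval arithmetic."""
    out = set()
    for l in lncs:
        for g in genes:
            if l.chrom != g.chrom:
                continue
            ov = min(l.end, g.end) - max(l.start, g.start) + 1
            if ov >= 1:
                rel = "antisense" if l.strand != g.strand else "overlapping_sense"
                out.add((l.feature_id, g.feature_id, rel, 0, ov))
            else:
                if l.end < g.start:
                    d = g.start - l.end          # coordinate difference
                    upstream = g.strand == "+"
                else:
                    d = l.start - g.end
                    upstream = g.strand == "-"
                if d <= window:
                    rel = "upstream" if upstream else "downstream"
                    out.add((l.feature_id, g.feature_id, rel, d, 0))
    return out


def oracle_summary(lncs, genes, window=2000):
    pairs = oracle_pairs(lncs, genes, window)
    anti = {p[0] for p in pairs if p[2] == "antisense"}
    flank = {p[0] for p in pairs if p[2] in ("upstream", "downstream")} - anti
    anti_genes = {p[1] for p in pairs if p[2] == "antisense"}
    flank_genes = {p[1] for p in pairs
                   if p[2] in ("upstream", "downstream") and p[0] in flank}
    return len(anti), len(flank), len(anti_genes), len(flank_genes)


@st.composite
def random_fixture(draw):
    n_genes = draw(st.integers(1, 25))
    n_lncs = draw(st.integers(1, 25))
    chroms = ["c1", "c2"]

    def feat(i, kind):
        chrom = draw(st.sampled_from(chroms))
        start = draw(st.integers(1, 15000))
        min_len = 200 if kind == "lncRNA" else 50
        length = draw(st.integers(min_len, 3000))
        strand = draw(st.sampled_from("+-"))
        return GenomicFeature(f"{kind[0]}{i}", chrom, start,
                              start + length - 1, strand, kind)

    return ([feat(i, "lncRNA") for i in range(n_lncs)],
            [feat(i, "gene") for i in range(n_genes)])


class TestAntisense:
    def test_overlap_opposite_strand(self):
        g = F("g", "c", 1000, 2000, "+", "gene")
        l = F("l", "c", 1500, 2500, "-", "lncRNA")
        (rec,) = find_antisense(l, [g])
        assert (rec.relation, rec.overlap_len, rec.distance) == ("antisense", 501, 0)

    def test_same_strand_or_adjacent_is_not_antisense(self):
        g = F("g", "c", 1000, 2000, "+", "gene")
        assert find_antisense(F("l", "c", 1500, 2500, "+", "lncRNA"), [g]) == []
        assert find_antisense(F("l", "c", 2001, 2500, "-", "lncRNA"), [g]) == []


class TestFlanking:
    def test_upstream_coordinate_distance(self):
        # mirrors the published "located 1229 bp upstream" arithmetic
        g = F("g", "c", 5000, 8000, "+", "gene")
        l = F("l", "c", 3000, 3771, "+", "lncRNA")
        (rec,) = find_flanking(l, [g])
        assert (rec.relation, rec.distance) == ("upstream", 1229)

    def test_gene_strand_flips_label(self):
        g = F("g", "c", 5000, 8000, "-", "gene")
        l = F("l", "c", 3000, 3771, "+", "lncRNA")
        (rec,) = find_flanking(l, [g])
        assert (rec.relation, rec.distance) == ("downstream", 1229)

    @pytest.mark.parametrize("lnc_end, annotated", [(3000, True), (2999, False)])
    def test_window_boundary_inclusive(self, lnc_end, annotated):
        # distance 2000 annotates; 2001 does not
        g = F("g", "c", 5000, 8000, "+", "gene")
        l = F("l", "c", lnc_end - 500, lnc_end, "+", "lncRNA")
        recs = find_flanking(l, [g], window=2000)
        assert bool(recs) is annotated
        if annotated:
            assert recs[0].distance == 2000

    def test_gap_convention(self):
        g = F("g", "c", 5000, 8000, "+", "gene")
        l = F("l", "c", 3000, 3771, "+", "lncRNA")
        (rec,) = find_flanking(l, [g], distance_convention="gap")
        assert rec.distance == 1228


class TestAnnotateAll:
    def test_precedence_and_counts(self):
        genes = [F("gA", "c", 1000, 2000, "+", "gene"),
                 F("gB", "c", 4000, 5000, "+", "gene")]
        # antisense to gA and 500 bp upstream of gB
        lnc = F("l1", "c", 1500, 3500, "-", "lncRNA")
        records, summary = annotate_all([lnc], genes)
        assert {(r.gene_id, r.relation) for r in records} == {
            ("gA", "antisense"), ("gB", "upstream")}
        assert summary.n_antisense_lnc == 1 and summary.n_flank_lnc == 0
        assert summary.n_annotated_lnc == 1

    def test_empty_lnc_list(self):
        records, summary = annotate_all([], [F("g", "c", 1, 100, "+", "gene")])
        assert records == [] and summary.n_annotated_lnc == 0

    def test_duplicate_ids_rejected(self):
        g = F("g", "c", 1, 100, "+", "gene")
        l = F("l", "c", 200, 500, "+", "lncRNA")
        with pytest.raises(ValidationError):
            annotate_all([l, l], [g])

    def test_mixed_class_accounting(self):
        genes = [F(f"g{i}", "c", 10000 * i, 10000 * i + 1000, "+", "gene")
                 for i in range(1, 7)]
        lncs = (
            [F(f"a{i}", "c", 10000 * i + 100, 10000 * i + 400, "-", "lncRNA")
             for i in range(1, 4)]                       # 3 antisense
            + [F(f"f{i}", "c", 10000 * i - 900, 10000 * i - 500, "+", "lncRNA")
               for i in range(4, 6)]                     # 2 flanking
            + [F("u1", "c", 75000, 75400, "+", "lncRNA")]  # unannotated
        )
        _, summary = annotate_all(lncs, genes)
        assert summary.n_antisense_lnc == 3
        assert summary.n_flank_lnc == 2
        assert summary.n_annotated_lnc == 5

    @settings(max_examples=60)
    @given(random_fixture())
    def test_matches_all_pairs_oracle(self, fixture):
        lncs, genes = fixture
        records, summary = annotate_all(lncs, genes)
        got = {(r.lnc_id, r.gene_id, r.relation, r.distance, r.overlap_len)
               for r in records}
        assert got == oracle_pairs(lncs, genes)
        assert (summary.n_antisense_lnc, summary.n_flank_lnc,
                summary.n_antisense_genes, summary.n_flank_genes) == \
            oracle_summary(lncs, genes)

    @settings(max_examples=25)
    @given(random_fixture(), st.integers(0, 10000))
    def test_shift_invariance(self, fixture, shift):
        lncs, genes = fixture
        rec0, _ = annotate_all(lncs, genes)

        def shifted(f):
            return dataclasses.replace(f, start=f.start + shift,
                                       end=f.end + shift)

        rec1, _ = annotate_all([shifted(l) for l in lncs],
                               [shifted(g) for g in genes])
        assert rec0 == rec1

    @settings(max_examples=25)
    @given(random_fixture(), st.integers(0, 3000), st.integers(0, 3000))
    def test_window_monotonicity(self, fixture, w1, w2):
        lncs, genes = fixture
        lo, hi = sorted((w1, w2))
        rec_lo, _ = annotate_all(lncs, genes, window=max(lo, 1))
        rec_hi, _ = annotate_all(lncs, genes, window=max(hi, 1))
        assert set(rec_lo) <= set(rec_hi)
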