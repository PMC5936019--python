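"""Fold change, significance testing, BH correction and symbol calling."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncmem.core import ValidationError
from lncmem.diffexpr import (
    DEThresholds,
    benjamini_hochberg,
    call_symbol,
    compute_log2fc,
    moderated_ttest,
    run_contrast,
)
from lncmem.diffexpr import test_feature as welch_test

fpkm_lists = st.lists(
    st.floats(min_value=0, max_value=1e5, allow_nan=False), min_size=1, max_size=6)


class TestLog2FC:
    @pytest.mark.parametrize(
        "treat, ctrl, c, expected",
        [
            ([3, 3], [1, 1], 1.0, 1.0),        # log2(4/2)
            ([5, 7], [5, 7], 1.0, 0.0),        # identity
            ([0, 0], [0, 0], 1.0, 0.0),        # pseudocount guards 0/0
        ],
    )
    def test_examples(self, treat, ctrl, c, expected):
        assert compute_log2fc(treat, ctrl, c) == pytest.approx(expected)

    def test_empty_list_is_error(self):
        with pytest.raises(ValidationError):
            compute_log2fc([], [1.0])

    @given(treat=fpkm_lists, ctrl=fpkm_lists,
           c=st.floats(min_value=1e-3, max_value=10))
    def test_antisymmetry(self, treat, ctrl, c):
        assert compute_log2fc(treat, ctrl, c) == pytest.approx(
            -compute_log2fc(ctrl, treat, c), abs=1e-9)

    @given(vals=fpkm_lists, c=st.floats(min_value=1e-3, max_value=10))
    def test_zero_at_equal_means_for_any_pseudocount(self, vals, c):
        assert compute_log2fc(vals, list(vals), c) == 0.0


class TestFeatureTest:
    def test_identical_groups_give_p_one(self):
        assert welch_test([5, 5], [5, 5]) == 1.0

    def test_strong_separation_is_significant(self):
        assert welch_test([100, 102], [1, 1.1]) < 0.05

    def test_single_replicate_is_error(self):
        with pytest.raises(ValidationError, match="supplied-q"):
            welch_test([5.0], [1.0, 2.0])


class TestBH:
    def test_step_up_hand_example(self):
        # min over j >= i of m * p(j) / j: all collapse to 0.03
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_identity_and_zero(self):
        assert benjamini_hochberg([0.5]) == pytest.approx([0.5])
        assert benjamini_hochberg([0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_bounds(self, p, rand):
        q = benjamini_hochberg(p)
        assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1 + 1e-12).all()
        idx = list(range(len(p)))
        rand.shuffle(idx)
        q_perm = benjamini_hochberg([p[i] for i in idx])
        assert q_perm == pytest.approx([q[i] for i in idx])


class TestSymbol:
    @pytest.mark.parametrize(
        "lfc, q, expected",
        [(1.0, 0.05, "+"), (3.0, 0.2, "="), (-1.2, 0.01, "-"),
         (0.99, 0.01, "="), (-1.0, 0.05, "-")],
    )
    def test_inclusive_thresholds(self, lfc, q, expected):
        assert call_symbol(lfc, q, DEThresholds()) == expected

    @given(lfc=st.floats(-10, 10), q=st.floats(0, 1))
    def test_three_way_partition_exhaustive_exclusive(self, lfc, q):
        th = DEThresholds()
        s = call_symbol(lfc, q, th)
        assert s in ("+", "-", "=")
        matches = [
            lfc >= th.min_abs_log2fc and q <= th.max_q,
            lfc <= -th.min_abs_log2fc and q <= th.max_q,
        ]
        assert sum(matches) <= 1
        assert s == ("+", "-")[matches.index(True)] if any(matches) else s == "="


class TestRunContrast(object):
    def test_symbols_and_supplied_q_override(self, small_sim):
        recs = run_contrast(small_sim.matrix, ("D1", "C1"))
        assert len(recs) == len(small_sim.matrix.features)
        th = DEThresholds()
        for r in recs:
            assert r.symbol == call_symbol(r.log2fc, r.q, th)
        sq = small_sim.truth.supplied_q(("D1", "C1"))
        recs_sq = run_contrast(small_sim.matrix, ("D1", "C1"), supplied_q=sq)
        for r in recs_sq:
            assert r.q == sq.loc[r.feature_id, "q"]

    def test_unknown_treatment_is_error(self, small_sim):
        with pytest.raises(ValidationError):
            run_contrast(small_sim.matrix, ("D3", "C1"))

    def test_supplied_q_must_cover_all_features(self, small_sim):
        sq = small_sim.truth.supplied_q(("D1", "C1")).iloc[:-2]
        with pytest.raises(ValidationError, match="missing"):
            run_contrast(small_sim.matrix, ("D1", "C1"), supplied_q=sq)


class TestModeratedT:
    def test_degenerate_variance_rule(self):
        t, p = moderated_ttest(np.full((3, 2), 5.0), np.full((3, 2), 5.0))
        assert (p == 1.0).all()

    def test_matches_limma_reference(self, tmp_path, rng):
        """Cross-check the empirical-Bayes moderated t against the
        Bioconductor limma implementation on a random two-group matrix."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the limma cross-check")
        n = 60
        treat = rng.normal(4, 1, (n, 1)) + rng.normal(0, 0.3, (n, 2))
        ctrl = treat.mean(axis=1, keepdims=True) + rng.normal(0, 0.3, (n, 2))
        treat[: n // 4] += 1.5  # some true effects
        _, p_mine = moderated_ttest(treat, ctrl)

        mat = np.hstack([treat, ctrl])
        df = pd.DataFrame(mat, columns=["t1", "t2", "c1", "c2"])
        csv = tmp_path / "m.csv"
        df.to_csv(csv, index=False)
        rout = tmp_path / "p.csv"
        script = tmp_path / "limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.csv("{csv}"))
design <- cbind(Intercept=1, Treat=c(1,1,0,0))
fit <- eBayes(lmFit(m, design))
write.csv(data.frame(p=fit$p.value[,"Treat"]), "{rout}", row.names=FALSE)
""")
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True)
        p_limma = pd.read_csv(rout)["p"].to_numpy()
        assert p_mine == pytest.approx(p_limma, rel=1e-3, abs=1e-10)
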