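import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mir172tx import diffexpr
from mir172tx.diffexpr import Contrast, DEGSet, DEResult
from mir172tx.io_formats import CountMatrix


def bh_brute_force(p):
    """Step-up definition: padj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    padj_sorted = np.empty(m)
    for i in range(m):
        padj_sorted[i] = min(
            min(1.0, m * sorted_p[j] / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = padj_sorted
    return out


class TestAdjustBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            diffexpr.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        assert diffexpr.adjust_bh([0.5])[0] == pytest.approx(0.5)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            diffexpr.adjust_bh([0.5, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_step_up_definition(self, pvals):
        np.testing.assert_allclose(
            diffexpr.adjust_bh(pvals), bh_brute_force(pvals), atol=1e-12
        )

    def test_monotone_along_sorted_pvalues(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        padj = diffexpr.adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj <= 1).all() and (padj >= p - 1e-12).all()


def make_contrast_counts(treat, ctrl, genes=None):
    treat, ctrl = np.asarray(treat), np.asarray(ctrl)
    genes = genes or [f"g{i}" for i in range(treat.shape[0])]
    t_libs = [f"T{j}" for j in range(treat.shape[1])]
    c_libs = [f"C{j}" for j in range(ctrl.shape[1])]
    cm = CountMatrix(
        pd.DataFrame(
            np.hstack([treat, ctrl]).astype(np.int64), index=genes, columns=t_libs + c_libs
        )
    )
    contrast = Contrast("t_vs_c", ("A", "x", 1), ("B", "x", 1), t_libs, c_libs)
    return cm, contrast


class TestNbWaldTest:
    def test_identical_groups_have_zero_log2fc(self):
        rng = np.random.default_rng(1)
        block = rng.integers(1, 400, size=(50, 3))
        cm, contrast = make_contrast_counts(block, block)
        res = diffexpr.nb_wald_test(cm, contrast)
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 400, size=(60, 3))
        c = rng.integers(0, 400, size=(60, 3))
        cm, contrast = make_contrast_counts(t, c)
        fwd = diffexpr.nb_wald_test(cm, contrast)
        swapped = Contrast(
            "c_vs_t", contrast.control, contrast.treatment,
            contrast.control_libs, contrast.treatment_libs,
        )
        rev = diffexpr.nb_wald_test(cm, swapped)
        np.testing.assert_allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-10)
        np.testing.assert_allclose(fwd.table["pvalue"], rev.table["pvalue"], atol=1e-10)

    def test_all_zero_gene_gets_null_result(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 400, size=(30, 3))
        c = rng.integers(1, 400, size=(30, 3))
        t[5] = c[5] = 0
        cm, contrast = make_contrast_counts(t, c)
        res = diffexpr.nb_wald_test(cm, contrast)
        assert res.table["log2fc"].iloc[5] == 0.0
        assert res.table["pvalue"].iloc[5] == 1.0

    def test_contrast_validation(self):
        with pytest.raises(ValueError, match="overlapping"):
            Contrast("bad", ("A", "x", 1), ("B", "x", 1), ["L1", "L2"], ["L2", "L3"])
        with pytest.raises(ValueError, match=">= 2"):
            Contrast("bad", ("A", "x", 1), ("B", "x", 1), ["L1"], ["L2", "L3"])


def result_from_dict(name, lfc, padj=None):
    genes = list(lfc)
    table = pd.DataFrame(
        {
            "log2fc": [lfc[g] for g in genes],
            "pvalue": [0.001] * len(genes),
            "padj": [padj.get(g, 0.001) if padj else 0.001 for g in genes],
            "mean_treatment": 10.0,
            "mean_control": 10.0,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(contrast=name, table=table)


class TestCallDegs:
    def test_strict_boundaries(self):
        res = result_from_dict(
            "c", {"g1": 1.0, "g2": 3.0, "g3": 1.5, "g4": -1.2},
            padj={"g1": 0.049, "g2": 0.06, "g3": 0.01, "g4": 0.01},
        )
        ds = diffexpr.call_degs(res)
        assert ds.up == {"g3"}  # g1 excluded: log2fc == 1 exactly; g2: padj >= 0.05
        assert ds.down == {"g4"}

    def test_retained_set_restricts_calls(self):
        res = result_from_dict("c", {"g1": 2.0, "g2": 2.0})
        ds = diffexpr.call_degs(res, retained={"g2"})
        assert ds.all == {"g2"}


class TestMultiTissueClassification:
    def test_union_and_cross_tissue_discordance(self):
        fs = result_from_dict("FS", {"g1": 2.0, "g2": 1.5}, padj={"g1": 0.01, "g2": 0.01})
        fc = result_from_dict("FC", {"g1": 0.0, "g2": -2.5}, padj={"g1": 0.9, "g2": 0.01})
        per_tissue, combined = diffexpr.classify_multi_tissue({"FS": fs, "FC": fc})
        assert per_tissue["FS"].up == {"g1", "g2"}
        assert per_tissue["FC"].down == {"g2"}
        assert combined == {"g1", "g2"}  # discordant g2 counted once

    def test_empty_results_give_empty_combined(self):
        empty = result_from_dict("FS", {})
        _, combined = diffexpr.classify_multi_tissue({"FS": empty})
        assert combined == set()


class TestAssignDirection:
    def test_single_contrast_uses_its_sign(self):
        res = result_from_dict("c", {"g1": -2.0}, padj={"g1": 0.01})
        ds = diffexpr.call_degs(res)
        assert diffexpr.assign_direction({"c": ds}, {"c": res}) == {"g1": "down"}

    def test_max_abs_lfc_wins(self):
        fs = result_from_dict("FS", {"g1": 1.5}, padj={"g1": 0.01})
        fc = result_from_dict("FC", {"g1": -2.5}, padj={"g1": 0.01})
        dirs = diffexpr.assign_direction(
            {"FS": diffexpr.call_degs(fs), "FC": diffexpr.call_degs(fc)},
            {"FS": fs, "FC": fc},
        )
        assert dirs == {"g1": "down"}

    def test_tie_breaks_toward_up(self):
        fs = result_from_dict("FS", {"g1": 2.0}, padj={"g1": 0.01})
        fc = result_from_dict("FC", {"g1": -2.0}, padj={"g1": 0.01})
        dirs = diffexpr.assign_direction(
            {"FS": diffexpr.call_degs(fs), "FC": diffexpr.call_degs(fc)},
            {"FS": fs, "FC": fc},
        )
        assert dirs == {"g1": "up"}

    def test_missing_gene_raises(self):
        res = result_from_dict("c", {"g1": 2.0}, padj={"g1": 0.01})
        dirs = diffexpr.assign_direction({"c": diffexpr.call_degs(res)}, {"c": res})
        with pytest.raises(KeyError):
            diffexpr.direction_for_gene(dirs, "absent")


def test_degset_disjointness_enforced():
    with pytest.raises(ValueError):
        DEGSet("c", up={"g1"}, down={"g1"})
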