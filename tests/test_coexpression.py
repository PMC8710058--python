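import itertools

import numpy as np
import pandas as pd
import pytest

from mir172tx import coexpression
from mir172tx.coexpression import (
    CoexpressionNetwork,
    CorrelationEdge,
    build_network,
    find_mbw_motifs,
    guide_subnetwork,
    pairwise_pcc,
    screen_interaction_pairs,
)
from mir172tx.io_formats import GeneAnnotation


def exact_corr_profiles(rhos, n_libs=12, seed=0):
    """Log2 profiles: gene 'x' plus one gene per rho with sample corr exactly rho."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n_libs)
    u = (base - base.mean()) / np.linalg.norm(base - base.mean())
    mats = rng.normal(size=(n_libs, len(rhos)))
    profiles = {"x": u}
    for i, rho in enumerate(rhos):
        w = mats[:, i]
        w = w - w.mean()
        w = w - (w @ u) * u
        w /= np.linalg.norm(w)
        profiles[f"y{i}"] = rho * u + np.sqrt(1 - rho**2) * w
    # shift positive so 2^L - 1 >= 0
    shift = 1 + max(abs(v).max() for v in profiles.values())
    return {g: v + shift for g, v in profiles.items()}


def annot_for(families):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": list(families),
                "length_bp": [1000] * len(families),
                "family": list(families.values()),
            }
        )
    )


class TestPairwisePcc:
    def test_perfect_linear_relations(self, make_expr):
        expr = make_expr({"a": np.array([1.0, 2, 3, 4]), "b": np.array([2.0, 4, 6, 8]),
                          "c": np.array([9.0, 8, 7, 6])}, 4)
        pcc = pairwise_pcc(expr, ["a"], ["b", "c"])
        assert pcc.at["a", "b"] == pytest.approx(1.0)
        assert pcc.at["a", "c"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self, make_expr):
        rng = np.random.default_rng(1)
        profiles = {f"g{i}": rng.uniform(0, 8, size=10) for i in range(6)}
        expr = make_expr(profiles, 10)
        pcc = pairwise_pcc(expr, list(profiles), list(profiles))
        for a in profiles:
            for b in profiles:
                x, y = profiles[a], profiles[b]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert pcc.at[a, b] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance_and_symmetry(self, make_expr):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=8)
        y = rng.uniform(0, 5, size=8)
        expr = make_expr({"a": x, "b": y, "a2": 2.0 * x + 1.0}, 8)
        pcc = pairwise_pcc(expr, ["a", "b", "a2"], ["a", "b", "a2"])
        assert pcc.at["a", "b"] == pytest.approx(pcc.at["b", "a"])
        assert pcc.at["a2", "b"] == pytest.approx(pcc.at["a", "b"])

    def test_constant_gene_reported_missing(self, make_expr):
        expr = make_expr({"a": np.array([1.0, 2, 3, 4]), "flat": np.ones(4)}, 4)
        pcc = pairwise_pcc(expr, ["a"], ["flat"])
        assert np.isnan(pcc.at["a", "flat"])

    def test_requires_three_libraries(self, make_expr):
        expr = make_expr({"a": np.array([1.0, 2]), "b": np.array([2.0, 1])}, 2)
        with pytest.raises(ValueError, match="3 libraries"):
            pairwise_pcc(expr, ["a"], ["b"])


class TestScreenInteractionPairs:
    def matrix(self, entries, fill=0.5):
        genes_x = [f"arf{i}" for i in range(4)]
        genes_y = [f"iaa{j}" for j in range(4)]
        m = pd.DataFrame(fill, index=genes_x, columns=genes_y)
        for (i, j), v in entries.items():
            m.iat[i, j] = v
        return m

    def test_exactly_six_qualifying_pairs(self):
        entries = {(0, 0): 0.96, (0, 1): 0.97, (1, 2): -0.91, (2, 0): -0.94,
                   (2, 3): 0.93, (3, 1): -0.93}
        pairs = screen_interaction_pairs(self.matrix(entries))
        assert len(pairs) == 6
        assert pairs[0][2] == pytest.approx(0.97)  # sorted by |pcc| desc
        assert {abs(round(p, 2)) for _, _, p in pairs} == {0.96, 0.97, 0.91, 0.94, 0.93}

    def test_boundary_excluded(self):
        pairs = screen_interaction_pairs(self.matrix({(0, 0): 0.90, (1, 1): -0.90}))
        assert pairs == []

    def test_empty_matrix(self):
        assert screen_interaction_pairs(pd.DataFrame()) == []


class TestBuildNetwork:
    def test_asymmetric_cutoffs(self, make_expr):
        profiles = exact_corr_profiles([-0.85, 0.85, 0.92, 0.96])
        expr = make_expr(profiles, 12)
        net = build_network(expr, ["x"], ["y0", "y1", "y2", "y3"])
        kinds = {e.key: e.tier for e in net.edges}
        assert ("x", "y0") in kinds          # pcc -0.85 passes the -0.8 cutoff
        assert ("x", "y1") not in kinds      # pcc 0.85 fails the 0.9 cutoff
        assert kinds[("x", "y2")] == "standard"
        assert kinds[("x", "y3")] == "stringent"

    def test_edge_set_invariant_to_gene_order(self, make_expr):
        profiles = exact_corr_profiles([0.95, 0.93, -0.9])
        expr = make_expr(profiles, 12)
        genes = ["y0", "y1", "y2"]
        a = build_network(expr, ["x"], genes)
        b = build_network(expr, ["x"], genes[::-1])
        assert {e.key for e in a.edges} == {e.key for e in b.edges}

    def test_planted_module_is_densely_edged(self):
        """At module_rho clearly above the 0.9 edge cutoff, nearly every
        within-module structural-TF pair is edged. (At rho equal to the
        cutoff itself, roughly half the sample correlations fall below it,
        so the check is run at rho 0.95, pooled over three seeds.)"""
        from mir172tx import expression, synthetic

        edged = possible = 0
        for seed in (0, 1, 2):
            cfg = synthetic.SimulationConfig(n_genes=800, module_rho=0.95, seed=seed)
            counts, sheet, annot, truth = synthetic.simulate_counts(cfg)
            fpkm = expression.compute_fpkm(counts, annot)
            exp1 = list(
                sheet.data.loc[
                    sheet.data["genotype"].isin(["WT", "miR172OX"]), "library_id"
                ]
            )
            m1 = truth.module_members(1)
            fams = annot.families()
            structural = [g for g in m1 if fams[g] == "structural"]
            tfs = [g for g in m1 if fams[g] in ("MYB", "bHLH", "WD40")]
            net = build_network(fpkm, structural, tfs, exp1)
            edged += len(net.edges)
            possible += len(structural) * len(tfs)
        assert edged >= 0.8 * possible


class TestGuideSubnetwork:
    def test_k_exceeding_pool_takes_all_by_sign(self, make_expr):
        profiles = exact_corr_profiles([0.9, 0.5, -0.4, -0.8, 0.2])
        expr = make_expr(profiles, 12)
        sub = guide_subnetwork(expr, "x", [f"y{i}" for i in range(5)], k=10)
        assert set(sub.top_positive) == {"y0", "y1", "y4"}
        assert set(sub.top_negative) == {"y2", "y3"}

    def test_top_k_matches_brute_force(self, make_expr):
        rng = np.random.default_rng(3)
        for trial in range(20):
            profiles = {f"g{i}": rng.uniform(0, 6, size=10) for i in range(15)}
            profiles["guide"] = rng.uniform(0, 6, size=10)
            expr = make_expr(profiles, 10)
            cand = [g for g in profiles if g != "guide"]
            sub = guide_subnetwork(expr, "guide", cand, k=3)
            scores = {
                c: np.corrcoef(profiles["guide"], profiles[c])[0, 1] for c in cand
            }
            pos = sorted((c for c in cand if scores[c] > 0), key=lambda c: (-scores[c], c))[:3]
            neg = sorted((c for c in cand if scores[c] < 0), key=lambda c: (scores[c], c))[:3]
            assert sub.top_positive == pos
            assert sub.top_negative == neg

    def test_guide_excluded_from_candidates(self, make_expr):
        profiles = exact_corr_profiles([0.9])
        expr = make_expr(profiles, 12)
        sub = guide_subnetwork(expr, "x", ["x", "y0"], k=5)
        assert "x" not in sub.top_positive + sub.top_negative

    def test_constant_guide_is_an_error(self, make_expr):
        expr = make_expr({"flat": np.ones(6), "a": np.arange(6.0)}, 6)
        with pytest.raises(ValueError, match="constant"):
            guide_subnetwork(expr, "flat", ["a"])


class TestFindMbwMotifs:
    def random_network(self, rng, n_nodes):
        nodes = [f"n{i}" for i in range(n_nodes)]
        fams = {n: rng.choice(["MYB", "bHLH", "WD40", "none"]) for n in nodes}
        edges = []
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.4:
                pcc = rng.uniform(-1, 1)
                tier = "stringent" if rng.random() < 0.5 else "standard"
                edges.append(CorrelationEdge(a, b, pcc, tier))
        return CoexpressionNetwork(edges=edges, families=fams), fams

    def brute_force(self, net, fams):
        strong = {e.key: e.pcc for e in net.edges if e.tier == "stringent"}

        def linked(a, b):
            return (min(a, b), max(a, b)) in strong

        out = set()
        nodes = sorted(net.nodes)
        for m, b, w in itertools.permutations(nodes, 3):
            if fams[m] == "MYB" and fams[b] == "bHLH" and fams[w] == "WD40":
                if linked(m, b) and linked(m, w) and linked(b, w):
                    out.add((m, b, w))
        return out

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for trial in range(15):
            net, fams = self.random_network(rng, rng.integers(6, 30))
            found = {(m.myb, m.bhlh, m.wd40) for m in find_mbw_motifs(net)}
            assert found == self.brute_force(net, fams)

    def test_no_wd40_means_no_motif(self):
        edges = [
            CorrelationEdge("m", "b", 0.99, "stringent"),
            CorrelationEdge("m", "x", 0.98, "stringent"),
            CorrelationEdge("b", "x", 0.97, "stringent"),
        ]
        net = CoexpressionNetwork(
            edges=edges, families={"m": "MYB", "b": "bHLH", "x": "none"}
        )
        assert find_mbw_motifs(net) == []

    def test_sorted_by_weakest_link(self):
        edges = [
            CorrelationEdge("m1", "b1", 0.99, "stringent"),
            CorrelationEdge("m1", "w1", 0.98, "stringent"),
            CorrelationEdge("b1", "w1", 0.97, "stringent"),
            CorrelationEdge("m1", "w2", 0.99, "stringent"),
            CorrelationEdge("b1", "w2", 0.999, "stringent"),
        ]
        net = CoexpressionNetwork(
            edges=edges,
            families={"m1": "MYB", "b1": "bHLH", "w1": "WD40", "w2": "WD40"},
        )
        motifs = find_mbw_motifs(net)
        assert [m.wd40 for m in motifs] == ["w2", "w1"]


def test_self_loops_and_duplicate_edges_rejected():
    with pytest.raises(ValueError, match="self-loop"):
        CorrelationEdge("a", "a", 0.5)
    e1 = CorrelationEdge("a", "b", 0.5)
    e2 = CorrelationEdge("b", "a", 0.6)  # canonical ordering collapses these
    with pytest.raises(ValueError, match="duplicate"):
        CoexpressionNetwork(edges=[e1, e2])
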