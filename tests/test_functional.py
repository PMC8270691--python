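import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lupus_ssc import functional as fn
from lupus_ssc import simulate as sim
from lupus_ssc.io import GeneSet, GeneSetCollection


def make_reference_cohort(n_healthy=30, n_sle=20, n_genes=30, shift=None, seed=0):
    """Healthy reference + SLE samples, optionally shifting all genes."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    healthy = rng.normal(0, 1, size=(n_genes, n_healthy))
    sle = rng.normal(0, 1, size=(n_genes, n_sle))
    if shift is not None:
        sle = sle + shift
    cols = [f"H{i}V0" for i in range(n_healthy)] + [f"P{i}V0" for i in range(n_sle)]
    expr = pd.DataFrame(np.hstack([healthy, sle]), index=genes, columns=cols)
    rows = []
    for c in cols:
        state = "healthy" if c.startswith("H") else "SLE"
        rows.append(dict(patient_id=c[:-3], sample_id=c, visit_index=0, time_days=0.0,
                         sledai=0 if state == "healthy" else 6, state=state,
                         age_group="adult", sex="female", race="white",
                         drug_cs=False, drug_hc=False, drug_is=False, drug_ifnk=False,
                         cohort="ref"))
    clin = pd.DataFrame(rows)
    gs = GeneSetCollection([GeneSet("T_ALL", "all genes", frozenset(genes), "IFN")])
    return expr, clin, gs


class TestGedActivity:
    def test_shifted_term_activity_near_shift(self):
        expr, clin, gs = make_reference_cohort(shift=3.0, seed=1)
        act = fn.ged_activity(expr, clin, gs)
        sle_cols = [c for c in act.columns if c.startswith("P")]
        assert act.loc["T_ALL", sle_cols].mean() == pytest.approx(3.0, abs=0.25)

    def test_healthy_null_level_sqrt_2_over_pi(self):
        expr, clin, gs = make_reference_cohort(n_healthy=40, seed=2)
        act = fn.ged_activity(expr, clin, gs)
        h_cols = [c for c in act.columns if c.startswith("H")]
        assert act.loc["T_ALL", h_cols].mean() == pytest.approx(math.sqrt(2 / math.pi), abs=0.05)

    def test_zero_variance_gene_dropped_with_warning(self):
        expr, clin, gs = make_reference_cohort(seed=3)
        healthy_cols = [c for c in expr.columns if c.startswith("H")]
        expr.loc["G0", healthy_cols] = 7.0
        with pytest.warns(UserWarning, match="zero healthy variance"):
            act = fn.ged_activity(expr, clin, gs)
        assert act.shape[0] == 1  # term survives on the remaining genes

    def test_no_healthy_samples_rejected(self):
        expr, clin, gs = make_reference_cohort(seed=4)
        sle = clin[clin["state"] == "SLE"]
        with pytest.raises(ValueError, match="healthy"):
            fn.ged_activity(expr[sle["sample_id"]], sle, gs)

    def test_small_term_dropped(self):
        expr, clin, _ = make_reference_cohort(seed=5)
        gs = GeneSetCollection([GeneSet("T_TINY", "small", frozenset({"G0", "G1"}), "IFN"),
                                GeneSet("T_OK", "fine", frozenset({"G2", "G3", "G4"}), "IFN")])
        with pytest.warns(UserWarning, match="T_TINY"):
            act = fn.ged_activity(expr, clin, gs)
        assert list(act.index) == ["T_OK"]

    def test_activity_nonnegative_and_finite(self, small_cohort):
        expr, clin, truth = small_cohort
        gs = sim.planted_genesets(truth, seed=0)
        act = fn.ged_activity(expr, clin, gs)
        assert (act.to_numpy() >= 0).all()
        assert np.isfinite(act.to_numpy()).all()


class TestEnrichTerms:
    def test_matches_exact_tail_enumeration(self):
        # overlap k=4, term m=10, query n=10, background N=100
        background = [f"g{i}" for i in range(100)]
        term_genes = frozenset(background[:10])
        query = background[:4] + background[50:56]
        gs = GeneSetCollection([GeneSet("T", "t", term_genes)])
        out = fn.enrich_terms(query, gs, background)
        # brute force: sum over the hypergeometric support
        def comb(n, k):
            return math.comb(n, k)
        p_exact = sum(comb(10, k) * comb(90, 10 - k) for k in range(4, 11)) / comb(100, 10)
        assert out.loc["T", "p_value"] == pytest.approx(p_exact, rel=1e-12)

    def test_query_equals_term_is_most_significant(self):
        background = [f"g{i}" for i in range(60)]
        gs = GeneSetCollection([
            GeneSet("SELF", "self", frozenset(background[:6])),
            GeneSet("OTHER", "other", frozenset(background[30:40])),
        ])
        out = fn.enrich_terms(background[:6], gs, background)
        assert out.loc["SELF", "p_value"] < out.loc["OTHER", "p_value"]
        assert out.loc["SELF", "significant"]

    def test_disjoint_term_p_one(self):
        background = [f"g{i}" for i in range(30)]
        gs = GeneSetCollection([GeneSet("T", "t", frozenset(background[20:25]))])
        out = fn.enrich_terms(background[:5], gs, background)
        assert out.loc["T", "p_value"] == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        gs = GeneSetCollection([GeneSet("T", "t", frozenset({"a"}))])
        with pytest.raises(ValueError, match="background"):
            fn.enrich_terms([], gs, [])

    def test_query_outside_background_rejected(self):
        gs = GeneSetCollection([GeneSet("T", "t", frozenset({"a"}))])
        with pytest.raises(ValueError, match="outside background"):
            fn.enrich_terms(["zzz"], gs, ["a", "b"])


class TestSubtypeDeg:
    def test_null_subtype_controls_fdr(self):
        expr, clin, _ = make_reference_cohort(n_healthy=25, n_sle=25, n_genes=200, seed=6)
        labels = pd.Series({s: "null" for s in clin.loc[clin.state == "SLE", "sample_id"]})
        out = fn.subtype_deg(expr, labels, clin)
        assert out["null"]["deg"].mean() <= 0.05

    def test_small_subtype_skipped_with_warning(self):
        expr, clin, _ = make_reference_cohort(seed=7)
        sle_ids = clin.loc[clin.state == "SLE", "sample_id"].tolist()
        labels = pd.Series({sle_ids[0]: "tiny"})
        with pytest.warns(UserWarning, match="tiny"):
            out = fn.subtype_deg(expr, labels, clin)
        assert out == {}


class TestModuleProfile:
    def test_healthy_vs_healthy_delta_near_zero(self):
        expr, clin, gs = make_reference_cohort(n_healthy=30, n_sle=0, n_genes=30, seed=8)
        # call half the healthy samples a pseudo-subtype
        h = clin["sample_id"].tolist()
        labels = pd.Series({s: "pseudo" for s in h[:15]})
        act = fn.ged_activity(expr, clin, gs)
        prof = fn.module_profile(act, gs, labels, clin)
        row = prof[(prof.subtype == "pseudo") & (prof.module == "IFN")].iloc[0]
        assert abs(row["delta"]) < 0.15

    def test_missing_module_reported_nan(self, small_cohort):
        expr, clin, truth = small_cohort
        gs = sim.planted_genesets(truth, seed=0)
        act = fn.ged_activity(expr, clin, gs)
        # add a module with no surviving terms
        gs2 = GeneSetCollection(list(gs) + [GeneSet("TV", "viral", frozenset({"zz1", "zz2", "zz3"}), "viral")])
        labels = pd.Series({s: "x" for s in clin.loc[clin.state == "SLE", "sample_id"][:20]})
        prof = fn.module_profile(act, gs2, labels, clin)
        viral = prof[prof.module == "viral"]
        assert viral["delta"].isna().all()


class TestTermSimilarityAndNetwork:
    def _activity(self, rng, n_terms=6, n_samples=40):
        shared = rng.normal(size=n_samples)
        rows = [shared + rng.normal(0, 0.3, n_samples) for _ in range(n_terms // 2)]
        rows += [rng.normal(size=n_samples) for _ in range(n_terms - n_terms // 2)]
        return pd.DataFrame(rows, index=[f"T{i}" for i in range(n_terms)])

    def test_symmetric_unit_diagonal_bounded(self, rng):
        act = self._activity(rng)
        simm, n = fn.term_similarity(act)
        arr = simm.to_numpy()
        assert n == act.shape[1]
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 1.0)
        assert (np.abs(arr) <= 1.0 + 1e-12).all()

    def test_constant_term_zeroed_with_warning(self, rng):
        act = self._activity(rng)
        act.loc["T0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            simm, _ = fn.term_similarity(act)
        assert (simm.loc["T0"].drop("T0") == 0).all()

    def test_too_few_samples_rejected(self, rng):
        act = self._activity(rng, n_samples=5)
        with pytest.raises(ValueError, match=">= 10"):
            fn.term_similarity(act)

    def test_shared_factor_terms_similar(self, rng):
        act = self._activity(rng, n_samples=100)
        simm, _ = fn.term_similarity(act)
        assert simm.loc["T0", "T1"] > 0.8

    def test_r_min_one_keeps_only_perfect_pairs(self, rng):
        act = self._activity(rng)
        act.loc["T5"] = act.loc["T4"]  # perfectly correlated pair
        simm, n = fn.term_similarity(act)
        G = fn.build_network(simm, n, r_min=1.0)
        assert set(map(frozenset, G.edges())) == {frozenset({"T4", "T5"})}

    def test_edge_count_monotone_in_r_min(self, rng):
        act = self._activity(rng)
        simm, n = fn.term_similarity(act)
        counts = [fn.build_network(simm, n, r_min=r).number_of_edges()
                  for r in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)


class TestCommunitiesAndBridges:
    def _two_cliques(self):
        G = nx.Graph()
        for base in ("a", "b"):
            nodes = [f"{base}{i}" for i in range(4)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    G.add_edge(u, v, weight=0.9)
        return G

    def test_disconnected_cliques_are_two_communities(self):
        G = self._two_cliques()
        comm, q = fn.detect_communities(G)
        assert len(set(comm.values())) == 2
        assert len({comm[f"a{i}"] for i in range(4)}) == 1
        assert q > 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            fn.detect_communities(nx.Graph())

    def test_single_edge_graph_no_crash(self):
        G = nx.Graph()
        G.add_edge("x", "y", weight=0.7)
        comm, q = fn.detect_communities(G)
        assert set(comm) == {"x", "y"}

    def test_barbell_path_node_is_top_bridge(self):
        G = self._two_cliques()
        G.add_edge("a0", "bridge", weight=0.8)
        G.add_edge("bridge", "b0", weight=0.8)
        comm, _ = fn.detect_communities(G)
        ranked = fn.bridge_nodes(G, comm, top_n=3)
        assert ranked[0][0] == "bridge"

    def test_disconnected_communities_no_bridges(self):
        G = self._two_cliques()
        comm, _ = fn.detect_communities(G)
        assert fn.bridge_nodes(G, comm) == []

    def test_single_community_warns_empty(self):
        G = nx.Graph()
        G.add_edge("x", "y", weight=1.0)
        with pytest.warns(UserWarning, match="one community"):
            assert fn.bridge_nodes(G, {"x": 0, "y": 0}) == []


class TestPlantedFactorPipeline:
    def test_two_factor_design_recovered(self):
        expr, clin, gs, truth = sim.generate_module_factor_design(seed=17)
        act = fn.ged_activity(expr, clin, gs)
        mixed = [c for c in act.columns if c.startswith("M")]
        simm, n = fn.term_similarity(act, mixed)
        G = fn.build_network(simm, n)
        comm, _ = fn.detect_communities(G)
        factor = {t: f for t, f in truth.items() if f in ("IFN", "NE")}
        assert len({comm[t] for t in factor}) == 2
        for a in factor:
            for b in factor:
                if a < b:
                    assert (comm[a] == comm[b]) == (factor[a] == factor[b])
        bridges = [t for t, _ in fn.bridge_nodes(G, comm, top_n=5)]
        assert "BRIDGE_T" in bridges
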