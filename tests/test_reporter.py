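"""Bipartite metabolite-enzyme graph and reporter scoring."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from msh.reporter import (
    ExpressionStats,
    build_graph,
    enzyme_z_scores,
    pvalue_to_z,
    score_metabolites,
)
from msh.synth import make_expression_dataset, make_single_substrate_model


class TestExpressionStats:
    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            ExpressionStats(pd.DataFrame({"gene_id": ["a"], "pvalue": [0.0]}))
        with pytest.raises(ValueError):
            ExpressionStats(pd.DataFrame({"gene_id": ["a"], "pvalue": [1.2]}))

    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValueError):
            ExpressionStats(pd.DataFrame({"gene_id": ["a", "a"], "pvalue": [0.1, 0.2]}))

    def test_tsv_round_trip(self, tmp_path):
        stats = ExpressionStats(pd.DataFrame({"gene_id": ["a", "b"], "pvalue": [0.5, 0.01]}))
        path = tmp_path / "expr.tsv"
        stats.write_tsv(path)
        back = ExpressionStats.read_tsv(path)
        pd.testing.assert_frame_equal(back.table, stats.table)


class TestBuildGraph:
    def test_toy_aerobe_matches_hand_enumeration(self, toy_models):
        """Node and edge sets of the toy aerobe graph, enumerated by hand:
        six gene-associated reactions; glucose, oligosaccharide, acetate and
        lactate as metabolite nodes (O2/CO2 are currency, biomass is a
        pseudo-metabolite); ten edges."""
        g = build_graph(toy_models["aerobe"])
        mets = {n for n, a in g.nodes(data=True) if a["kind"] == "metabolite"}
        enzymes = {n for n, a in g.nodes(data=True) if a["kind"] == "enzyme"}
        assert mets == {"glc_e", "oligo_e", "ac_e", "lac_e"}
        assert enzymes == {"GLC_AEROBIC", "GLC_FERMENT", "OLIGO_AEROBIC",
                           "OLIGO_FERMENT", "AC_OXIDATION", "LAC_OXIDATION"}
        expected_edges = {
            ("GLC_AEROBIC", "glc_e"),
            ("GLC_FERMENT", "glc_e"), ("GLC_FERMENT", "ac_e"), ("GLC_FERMENT", "lac_e"),
            ("OLIGO_AEROBIC", "oligo_e"),
            ("OLIGO_FERMENT", "oligo_e"), ("OLIGO_FERMENT", "ac_e"), ("OLIGO_FERMENT", "lac_e"),
            ("AC_OXIDATION", "ac_e"), ("LAC_OXIDATION", "lac_e"),
        }
        assert {tuple(sorted(e)) for e in g.edges()} == {tuple(sorted(e)) for e in expected_edges}
        # bipartite: every edge joins an enzyme to a metabolite
        for u, v in g.edges():
            assert {g.nodes[u]["kind"], g.nodes[v]["kind"]} == {"enzyme", "metabolite"}

    def test_reaction_without_genes_absent(self, toy_models):
        g = build_graph(toy_models["aerobe"])
        assert "BIOMASS_aerobe" not in g
        assert "EX_glc" not in g

    def test_model_without_gene_links_rejected(self):
        with pytest.raises(ValueError, match="gene"):
            build_graph(make_single_substrate_model())


class TestPvalueToZ:
    def test_median_maps_to_zero(self):
        assert pvalue_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_known_quantile(self):
        assert pvalue_to_z(0.0228) == pytest.approx(2.00, abs=5e-3)

    def test_boundary_p_one_guarded(self):
        z = pvalue_to_z(1.0)
        assert np.isfinite(z) and z < -8

    def test_out_of_range_rejected(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pvalue_to_z(p)

    def test_tiny_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = pvalue_to_z(1e-300)
        assert np.isfinite(z)


def _star_graph(k, z_targets):
    """One metabolite with k single-gene enzyme neighbours."""
    g = nx.Graph()
    g.add_node("met", kind="metabolite")
    rows = []
    from scipy.stats import norm

    for i, z in enumerate(z_targets):
        enz = f"enz{i}"
        g.add_node(enz, kind="enzyme", genes=[f"g{i}"])
        g.add_edge("met", enz)
        rows.append({"gene_id": f"g{i}", "pvalue": float(norm.sf(z))})
    return g, ExpressionStats(pd.DataFrame(rows))


class TestScoreMetabolites:
    def test_single_neighbor_same_under_both_normalizations(self):
        g, stats = _star_graph(1, [2.0])
        for normalization in ("mean", "sqrt_k"):
            sc = score_metabolites(g, stats, normalization=normalization)
            assert sc.table.iloc[0]["z"] == pytest.approx(2.0, abs=1e-9)

    def test_four_neighbors_mean_vs_sqrt_k(self):
        g, stats = _star_graph(4, [1.0, 1.0, 1.0, 1.0])
        mean = score_metabolites(g, stats, normalization="mean").table.iloc[0]["z"]
        sqrt_k = score_metabolites(g, stats, normalization="sqrt_k").table.iloc[0]["z"]
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert sqrt_k == pytest.approx(2.0, abs=1e-9)

    def test_enzyme_takes_best_gene_pvalue(self):
        g = nx.Graph()
        g.add_node("met", kind="metabolite")
        g.add_node("enz", kind="enzyme", genes=["g1", "g2"])
        g.add_edge("met", "enz")
        stats = ExpressionStats(pd.DataFrame({"gene_id": ["g1", "g2"], "pvalue": [0.5, 0.0228]}))
        assert enzyme_z_scores(g, stats)["enz"] == pytest.approx(pvalue_to_z(0.0228))

    def test_planted_metabolite_ranked_first(self, toy_models):
        g = build_graph(toy_models["aerobe"])
        stats = make_expression_dataset(g, ["glc_e"], effect_p=1e-4, seed=11)
        for normalization in ("mean", "sqrt_k"):
            sc = score_metabolites(g, stats, normalization=normalization)
            assert sc.table.iloc[0]["metabolite"] == "glc_e"

    def test_invariant_to_node_ordering(self, toy_models):
        g = build_graph(toy_models["aerobe"])
        stats = make_expression_dataset(g, ["ac_e"], effect_p=1e-3, seed=2)
        shuffled = nx.Graph()
        order = sorted(g.nodes, reverse=True)
        for n in order:
            shuffled.add_node(n, **g.nodes[n])
        shuffled.add_edges_from(reversed(list(g.edges())))
        a = score_metabolites(g, stats, seed=0).table
        b = score_metabolites(shuffled, stats, seed=0).table
        pd.testing.assert_frame_equal(a, b)

    def test_null_permutation_mean_near_zero(self):
        """Permuting gene labels yields corrected sqrt_k scores with mean
        close to zero (|mean| < 0.1 over 1000 seeded permutation draws).

        Uses a random bipartite graph large enough for the background
        standardisation to be well estimated."""
        from msh.synth import make_random_bipartite_graph

        g = make_random_bipartite_graph(seed=0)
        stats = make_expression_dataset(g, [], seed=0)
        genes = stats.table["gene_id"].to_numpy()
        pvals = stats.table["pvalue"].to_numpy()
        rng = np.random.default_rng(123)
        means = []
        for i in range(1000):
            perm = ExpressionStats(
                pd.DataFrame({"gene_id": genes, "pvalue": rng.permutation(pvals)})
            )
            sc = score_metabolites(
                g, perm, normalization="sqrt_k",
                background_correction=True, n_background=200, seed=i,
            )
            means.append(sc.table["z"].mean())
        assert abs(np.mean(means)) < 0.1

    def test_unscored_neighbourhood_excluded_and_counted(self, toy_models):
        """A metabolite whose enzymes carry no mapped p-value is dropped
        from the ranking and counted as excluded."""
        g = build_graph(toy_models["aerobe"])
        # only the glucose enzymes' genes are measured
        stats = ExpressionStats(
            pd.DataFrame({"gene_id": ["ga_ptsG", "ga_pflB"], "pvalue": [0.2, 0.3]})
        )
        sc = score_metabolites(g, stats)
        assert "oligo_e" not in set(sc.table["metabolite"])
        assert sc.excluded == 1  # oligo_e; ac/lac stay via the fermentation enzyme
        assert {"glc_e", "ac_e", "lac_e"} == set(sc.table["metabolite"])

    def test_no_scored_enzymes_rejected(self, toy_models):
        g = build_graph(toy_models["aerobe"])
        stats = ExpressionStats(pd.DataFrame({"gene_id": ["zz"], "pvalue": [0.5]}))
        with pytest.raises(ValueError, match="no enzyme"):
            score_metabolites(g, stats)
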