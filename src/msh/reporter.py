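"""Reporter-metabolite scoring of transcriptional regulation.

The metabolic network is cast as a bipartite undirected graph of
metabolite and enzyme nodes (one enzyme node per gene-associated
reaction, edges to its substrates and products).  Gene-level differential
expression p-values are mapped onto enzyme nodes via the inverse normal
cumulative distribution, Z = Phi^-1(1 - p), and each metabolite is scored
by aggregating the Z-scores of its k neighbouring enzymes.  Metabolites
with the highest scores mark the pathways most substantially regulated
between community states.

Two normalisations are provided: ``mean`` (1/k * sum Z_i) and ``sqrt_k``
(1/sqrt(k) * sum Z_i, the Patil-Nielsen form, under which a null
neighbourhood keeps unit variance).  An optional background correction
standardises each score against random same-size enzyme sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import StoichiometricModel

#: ubiquitous cofactors/byproducts excluded from metabolite nodes, matched
#: on the ID stem before the compartment suffix
DEFAULT_CURRENCY = frozenset(
    {"h", "h2o", "atp", "adp", "amp", "pi", "ppi", "nad", "nadh",
     "nadp", "nadph", "co2", "coa", "o2"}
)
#: biomass-precursor pseudo-metabolites are likewise structural, not chemical
PSEUDO_PREFIXES = ("bm", "biomass")

P_FLOOR = 1e-16


@dataclass
class ExpressionStats:
    """Gene-level differential-expression statistics.

    ``table`` columns: ``gene_id``, ``pvalue`` (two-tailed, in (0, 1]),
    optional ``log2fc`` and ``tpm``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if not {"gene_id", "pvalue"} <= set(t.columns):
            raise ValueError("expression table needs gene_id and pvalue columns")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene IDs in expression table")
        p = t["pvalue"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionStats":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def pvalues(self) -> dict:
        return dict(zip(self.table["gene_id"], self.table["pvalue"]))


def _stem(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0].lower()


def build_graph(
    model: StoichiometricModel,
    currency: frozenset = DEFAULT_CURRENCY,
) -> nx.Graph:
    """Bipartite metabolite-enzyme graph from a stoichiometric model.

    One enzyme node per gene-associated reaction, with edges to every
    metabolite the reaction consumes or produces.  Currency metabolites
    and biomass pseudo-metabolites are excluded (they would otherwise
    dominate node degree).  Node attributes: ``kind`` ("metabolite" or
    "enzyme"); enzyme nodes carry their ``genes`` list.
    """
    if not model.gene_reaction_links:
        raise ValueError(f"{model.model_id}: model has no gene-reaction links")
    g = nx.Graph()
    for rxn, genes in model.gene_reaction_links.items():
        if not genes:
            continue
        j = model.reaction_index(rxn)
        col = model.S.getcol(j).tocoo()
        mets = [model.metabolites[i] for i in col.row]
        mets = [
            m for m in mets
            if _stem(m) not in currency and not _stem(m).startswith(PSEUDO_PREFIXES)
        ]
        if not mets:
            continue
        g.add_node(rxn, kind="enzyme", genes=list(genes))
        for m in mets:
            g.add_node(m, kind="metabolite")
            g.add_edge(rxn, m)
    return g


def pvalue_to_z(p: float, floor: float = P_FLOOR) -> float:
    """Z = Phi^-1(1 - p), the inverse normal CDF of the p-value.

    p = 0.5 maps to 0; smaller p to larger Z.  p in (0, floor) is clamped
    with a warning (p = 1 maps to the floor's negative tail analogously).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p!r} outside (0, 1]")
    if p < floor:
        warnings.warn(f"p-value {p:g} below floor {floor:g}; clamped")
        p = floor
    p = min(p, 1.0 - floor)
    return float(norm.isf(p))


@dataclass
class ReporterScores:
    """Ranked metabolite scores; ``table`` columns: metabolite, z, k, rank."""

    table: pd.DataFrame
    normalization: str
    background_corrected: bool
    excluded: int = 0  # metabolites with no scored neighbour

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enzyme_z_scores(graph: nx.Graph, stats: ExpressionStats, floor: float = P_FLOOR) -> dict:
    """Per-enzyme Z from its genes' p-values (best = smallest p wins)."""
    pvals = stats.pvalues()
    out = {}
    for node, attrs in graph.nodes(data=True):
        if attrs.get("kind") != "enzyme":
            continue
        ps = [pvals[g] for g in attrs["genes"] if g in pvals]
        if ps:
            out[node] = pvalue_to_z(min(ps), floor)
    return out


def score_metabolites(
    graph: nx.Graph,
    stats: ExpressionStats,
    normalization: str = "mean",
    background_correction: bool = False,
    n_background: int = 1000,
    seed: int = 0,
) -> ReporterScores:
    """Score metabolites by their neighbouring enzymes' expression change.

    ``normalization="mean"`` aggregates neighbour Z-scores as
    (1/k) sum Z_i; ``"sqrt_k"`` as (1/sqrt(k)) sum Z_i.  With
    ``background_correction`` each score is centred and scaled by the
    aggregate of ``n_background`` random same-size enzyme sets (seeded),
    so scores are comparable across degrees.  Metabolites whose enzymes
    carry no mapped p-value are excluded and counted.
    """
    if normalization not in ("mean", "sqrt_k"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ez = enzyme_z_scores(graph, stats)
    if not ez:
        raise ValueError("no enzyme node has a mapped gene p-value")
    z_pool = np.array(list(ez.values()))
    rng = np.random.default_rng(seed)

    def aggregate(z_sum, k):
        return z_sum / k if normalization == "mean" else z_sum / np.sqrt(k)

    bg_cache = {}

    def background(k):
        if k not in bg_cache:
            draws = rng.choice(z_pool, size=(n_background, k), replace=True)
            agg = aggregate(draws.sum(axis=1), k)
            bg_cache[k] = (float(agg.mean()), float(agg.std(ddof=0)) or 1.0)
        return bg_cache[k]

    rows = []
    excluded = 0
    for node, attrs in sorted(graph.nodes(data=True)):
        if attrs.get("kind") != "metabolite":
            continue
        zs = [ez[e] for e in graph.neighbors(node) if e in ez]
        if not zs:
            excluded += 1
            continue
        k = len(zs)
        score = aggregate(float(np.sum(zs)), k)
        if background_correction:
            m, s = background(k)
            score = (score - m) / s
        rows.append({"metabolite": node, "z": score, "k": k})
    table = pd.DataFrame(rows).sort_values("z", ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ReporterScores(
        table=table,
        normalization=normalization,
        background_corrected=background_correction,
        excluded=excluded,
    )


def write_edge_list(graph: nx.Graph, path) -> None:
    """Plain-text bipartite edge list (enzyme <tab> metabolite)."""
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            if graph.nodes[u].get("kind") == "enzyme":
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{v}\t{u}\n")
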