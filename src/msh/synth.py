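"""Synthetic inputs: toy community models, batch growth curves, and
expression tables with planted differential neighbourhoods.

The toy aerobe/anaerobe pair reproduces the coupling structure of the
modelled gut community with lumped carbon bookkeeping:

* the facultative **aerobe** grows on glucose (aerobically or by
  fermentation, secreting acetate and lactate), on oligosaccharides, and
  aerobically on acetate and lactate; its oxygen demand ties carbon
  oxidation to the dissolved-O2 supply;
* the obligate **anaerobe** hydrolyses dextran (lumped as 100 glucose
  units) in a single reaction, releasing a configurable fraction of the
  glucose to the shared pool and secreting oligosaccharides and
  short-chain fatty acids; it has no oxygen exchange, and its growth is
  gated on dissolved O2 by the community simulation.

Every reaction is carbon-closed by construction (CO2 takes up the
balance), so the community's carbon audit is exact.  Yields are
per-mmol-substrate biomass yields (gCDW/mmol) on a 40 mmol C/gCDW biomass
basis; defaults are ordinary heterotroph values, with the oxygen transfer
calibration chosen so the community sits in the multistable regime of the
reactor (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fba import KineticParams
from .models import StoichiometricModel
from .monod import GrowthCurveSet, Well, simulate_batch
from .reporter import ExpressionStats

#: carbon atoms per molecule of each lumped species
CARBON = {"glc_e": 6.0, "oligo_e": 24.0, "ac_e": 2.0, "lac_e": 3.0,
          "co2_e": 1.0, "o2_e": 0.0}
#: biomass carbon content, mmol C per gCDW
BIOMASS_CARBON = 40.0
#: glucose units per oligosaccharide (the anaerobe's shared hydrolysate)
OLIGO_GLUCOSE_UNITS = 4

#: dextran: 1 g/L of a 100-unit glucan, in mM (anhydroglucose MW 162)
DEXTRAN_FEED_MM = 1.0 / (100 * 162.0) * 1000.0


class ToySpecError(ValueError):
    pass


@dataclass
class ToyCommunitySpec:
    """Yield and secretion parameters of the toy community.

    Yields in gCDW per mmol substrate; O2 demands in mmol O2 per mmol
    substrate oxidised; fermentation products in mmol per mmol glucose;
    the anaerobe's secretion split as carbon fractions of the residual
    (non-released, non-biomass) dextran carbon.
    """

    # aerobe
    yield_glucose_aerobic: float = 0.09
    yield_glucose_anaerobic: float = 0.025
    yield_acetate: float = 0.02
    yield_lactate: float = 0.03
    o2_per_glucose: float = 2.0
    o2_per_acetate: float = 0.8
    o2_per_lactate: float = 1.2
    ferment_acetate_per_glucose: float = 1.5
    ferment_lactate_per_glucose: float = 2.0 / 3.0
    # anaerobe
    yield_anaerobe_glucose: float = 0.04  # on dextran-derived internal glucose
    dextran_glucose_units: int = 100
    dextran_release_fraction: float = 0.5
    secretion_oligo_c_frac: float = 6.0 / 11.0
    secretion_acetate_c_frac: float = 3.0 / 11.0
    secretion_lactate_c_frac: float = 3.0 / 22.0
    seed: int = 0

    def __post_init__(self):
        for name in ("yield_glucose_aerobic", "yield_glucose_anaerobic",
                     "yield_acetate", "yield_lactate", "yield_anaerobe_glucose"):
            if getattr(self, name) <= 0:
                raise ToySpecError(f"{name} must be > 0")
        frac_sum = (self.secretion_oligo_c_frac + self.secretion_acetate_c_frac
                    + self.secretion_lactate_c_frac)
        if not 0 <= frac_sum <= 1:
            raise ToySpecError("secretion carbon fractions must sum to <= 1")
        if not 0 <= self.dextran_release_fraction <= 1:
            raise ToySpecError("dextran release fraction must be in [0, 1]")


def _closure_co2(substrate_c: float, *product_c: float) -> float:
    co2 = substrate_c - sum(product_c)
    if co2 < -1e-9:
        raise ToySpecError(
            f"carbon-infeasible reaction: products need {sum(product_c):.3f} C "
            f"but substrate provides {substrate_c:.3f}"
        )
    return max(co2, 0.0)


def _model(model_id, reactions, exchanges, genes, extra_carbon=None):
    carbon = dict(CARBON)
    if extra_carbon:
        carbon.update(extra_carbon)
    mets = sorted({m for _, stoich, _, _ in reactions for m in stoich})
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals, lbs, ubs = [], [], [], [], []
    rxn_ids = []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        rxn_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, v in stoich.items():
            rows.append(midx[met])
            cols.append(j)
            vals.append(v)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(f"BIOMASS_{model_id}")] = 1.0
    comp = {m: ("e" if m.endswith("_e") else "c") for m in mets}
    return StoichiometricModel(
        model_id=model_id,
        metabolites=mets,
        reactions=rxn_ids,
        S=sp.coo_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_ids))),
        lower_bounds=np.array(lbs, dtype=float),
        upper_bounds=np.array(ubs, dtype=float),
        objective=c,
        exchange_map=exchanges,
        gene_reaction_links=genes,
        compartments=comp,
        carbon={m: carbon.get(m, 0.0) for m in mets},
    )


def make_toy_models(spec: ToyCommunitySpec | None = None):
    """Build the (aerobe, anaerobe) toy model pair.

    Both models pass :class:`StoichiometricModel` validation and are
    carbon-balanced reaction by reaction.  Raises :class:`ToySpecError`
    when the requested yields exceed the available carbon.
    """
    if spec is None:
        spec = ToyCommunitySpec()
    BM = BIOMASS_CARBON
    BIG = 1000.0

    # --- aerobe ----------------------------------------------------------
    co2_ga = _closure_co2(6.0, BM * spec.yield_glucose_aerobic)
    co2_gn = _closure_co2(
        6.0,
        BM * spec.yield_glucose_anaerobic,
        2.0 * spec.ferment_acetate_per_glucose,
        3.0 * spec.ferment_lactate_per_glucose,
    )
    u = OLIGO_GLUCOSE_UNITS
    co2_oa = _closure_co2(6.0 * u, BM * u * spec.yield_glucose_aerobic)
    co2_on = _closure_co2(
        6.0 * u,
        BM * u * spec.yield_glucose_anaerobic,
        2.0 * u * spec.ferment_acetate_per_glucose,
        3.0 * u * spec.ferment_lactate_per_glucose,
    )
    co2_ac = _closure_co2(2.0, BM * spec.yield_acetate)
    co2_lac = _closure_co2(3.0, BM * spec.yield_lactate)
    aerobe_rxns = [
        ("GLC_AEROBIC",
         {"glc_e": -1.0, "o2_e": -spec.o2_per_glucose,
          "bm_aerobe": spec.yield_glucose_aerobic, "co2_e": co2_ga}, 0.0, BIG),
        ("GLC_FERMENT",
         {"glc_e": -1.0, "bm_aerobe": spec.yield_glucose_anaerobic,
          "ac_e": spec.ferment_acetate_per_glucose,
          "lac_e": spec.ferment_lactate_per_glucose, "co2_e": co2_gn}, 0.0, BIG),
        ("OLIGO_AEROBIC",
         {"oligo_e": -1.0, "o2_e": -u * spec.o2_per_glucose,
          "bm_aerobe": u * spec.yield_glucose_aerobic, "co2_e": co2_oa}, 0.0, BIG),
        ("OLIGO_FERMENT",
         {"oligo_e": -1.0, "bm_aerobe": u * spec.yield_glucose_anaerobic,
          "ac_e": u * spec.ferment_acetate_per_glucose,
          "lac_e": u * spec.ferment_lactate_per_glucose, "co2_e": co2_on}, 0.0, BIG),
        ("AC_OXIDATION",
         {"ac_e": -1.0, "o2_e": -spec.o2_per_acetate,
          "bm_aerobe": spec.yield_acetate, "co2_e": co2_ac}, 0.0, BIG),
        ("LAC_OXIDATION",
         {"lac_e": -1.0, "o2_e": -spec.o2_per_lactate,
          "bm_aerobe": spec.yield_lactate, "co2_e": co2_lac}, 0.0, BIG),
        ("BIOMASS_aerobe", {"bm_aerobe": -1.0}, 0.0, BIG),
        ("EX_glc", {"glc_e": -1.0}, -BIG, 0.0),
        ("EX_oligo", {"oligo_e": -1.0}, -BIG, 0.0),
        ("EX_ac", {"ac_e": -1.0}, -BIG, BIG),
        ("EX_lac", {"lac_e": -1.0}, -BIG, BIG),
        ("EX_o2", {"o2_e": -1.0}, -BIG, 0.0),
        ("EX_co2", {"co2_e": -1.0}, 0.0, BIG),
    ]
    aerobe_genes = {
        "GLC_AEROBIC": ["ga_ptsG", "ga_glk"],
        "GLC_FERMENT": ["ga_pflB"],
        "OLIGO_AEROBIC": ["ga_malZ"],
        "OLIGO_FERMENT": ["ga_malP"],
        "AC_OXIDATION": ["ga_actP", "ga_acs"],
        "LAC_OXIDATION": ["ga_lldD"],
    }
    aerobe = _model(
        "aerobe",
        aerobe_rxns,
        {"glc_e": "EX_glc", "oligo_e": "EX_oligo", "ac_e": "EX_ac",
         "lac_e": "EX_lac", "o2_e": "EX_o2"},
        aerobe_genes,
        extra_carbon={"bm_aerobe": BIOMASS_CARBON},
    )

    # --- anaerobe ---------------------------------------------------------
    n_units = spec.dextran_glucose_units
    f = spec.dextran_release_fraction
    dex_c = 6.0 * n_units
    released_glc = n_units * f
    bm_b = spec.yield_anaerobe_glucose * n_units * (1.0 - f)
    residual_c = dex_c - 6.0 * released_glc - BM * bm_b
    if residual_c < -1e-9:
        raise ToySpecError("anaerobe yield exceeds the dextran carbon balance")
    residual_c = max(residual_c, 0.0)
    s_oligo = residual_c * spec.secretion_oligo_c_frac / CARBON["oligo_e"]
    s_ac = residual_c * spec.secretion_acetate_c_frac / CARBON["ac_e"]
    s_lac = residual_c * spec.secretion_lactate_c_frac / CARBON["lac_e"]
    s_co2 = residual_c * (1.0 - spec.secretion_oligo_c_frac
                          - spec.secretion_acetate_c_frac
                          - spec.secretion_lactate_c_frac)
    anaerobe_rxns = [
        ("DEXTRAN_HYDROLYSIS",
         {"dex_e": -1.0, "glc_e": released_glc, "bm_anaerobe": bm_b,
          "oligo_e": s_oligo, "ac_e": s_ac, "lac_e": s_lac, "co2_e": s_co2},
         0.0, BIG),
        ("BIOMASS_anaerobe", {"bm_anaerobe": -1.0}, 0.0, BIG),
        ("EX_dex", {"dex_e": -1.0}, -BIG, 0.0),
        ("EX_glc", {"glc_e": -1.0}, 0.0, BIG),  # release only
        ("EX_oligo", {"oligo_e": -1.0}, 0.0, BIG),
        ("EX_ac", {"ac_e": -1.0}, 0.0, BIG),
        ("EX_lac", {"lac_e": -1.0}, 0.0, BIG),
        ("EX_co2", {"co2_e": -1.0}, 0.0, BIG),
    ]
    anaerobe_genes = {
        "DEXTRAN_HYDROLYSIS": ["an_dexA", "an_gaa"],
    }
    anaerobe = _model(
        "anaerobe",
        anaerobe_rxns,
        {"dex_e": "EX_dex", "glc_e": "EX_glc", "oligo_e": "EX_oligo",
         "ac_e": "EX_ac", "lac_e": "EX_lac"},
        anaerobe_genes,
        extra_carbon={"dex_e": dex_c, "bm_anaerobe": BIOMASS_CARBON},
    )
    return aerobe, anaerobe


def default_kinetics() -> KineticParams:
    """Michaelis-Menten defaults for the toy community.

    Carbon substrates use the literature defaults (v_max 10 mmol/gCDW/h,
    K_m 0.01 mM).  Oxygen uses a high-affinity terminal-oxidase entry
    (v_max 20, K_m 1e-4 mM = 100 nM) so respiration can draw dissolved O2
    below the anaerobe's 350 nM gate.  Dextran turnover is slow (v_max
    0.2 mmol/gCDW/h on the 100-glucose lump = 20 glucose units/gCDW/h),
    putting the anaerobe's maximum growth rate at ~0.4/h.
    """
    k = KineticParams()
    k.set("aerobe", "o2_e", 20.0, 1e-4)
    k.set("anaerobe", "dex_e", 0.2, 0.01)
    return k


def make_single_substrate_model(yield_gCDW_per_mmol: float = 0.09) -> StoichiometricModel:
    """Minimal one-substrate chemostat model (glucose -> biomass + CO2),
    used for closed-form chemostat validation."""
    y = yield_gCDW_per_mmol
    co2 = _closure_co2(6.0, BIOMASS_CARBON * y)
    rxns = [
        ("GLC_GROWTH", {"glc_e": -1.0, "bm_mono": y, "co2_e": co2}, 0.0, 1000.0),
        ("BIOMASS_mono", {"bm_mono": -1.0}, 0.0, 1000.0),
        ("EX_glc", {"glc_e": -1.0}, -1000.0, 0.0),
        ("EX_co2", {"co2_e": -1.0}, 0.0, 1000.0),
    ]
    return _model("mono", rxns, {"glc_e": "EX_glc"}, {},
                  extra_carbon={"bm_mono": BIOMASS_CARBON})


# ---------------------------------------------------------------------------
# growth curves


def make_growth_curves(
    mu_max: float = 0.6,
    K: float = 0.05,
    v_max: float = 0.6,
    substrate_grid=(0.125, 0.25, 0.375, 0.5),
    X0: float = 0.005,
    background: float = 0.05,
    duration_h: float = 16.0,
    sample_interval_h: float = 1.0 / 6.0,
    noise_sd: float = 0.005,
    seed: int = 0,
    species: str = "toy",
    carbon_source: str = "glucose",
) -> GrowthCurveSet:
    """Noisy Monod batch curves at several substrate concentrations.

    One well per concentration in ``substrate_grid`` (% w/v), OD sampled
    every 10 minutes, i.i.d. Gaussian noise of scale ``noise_sd`` added;
    fully reproducible from ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, sample_interval_h)
    wells = []
    for s0 in substrate_grid:
        od = simulate_batch(mu_max, K, v_max, X0, s0, times, background)
        od = od + rng.normal(0.0, noise_sd, size=od.shape) if noise_sd else od
        wells.append(Well(float(s0), times, np.maximum(od, 0.0)))
    return GrowthCurveSet(wells, species=species, carbon_source=carbon_source)


# ---------------------------------------------------------------------------
# expression tables


def make_random_bipartite_graph(
    n_metabolites: int = 40,
    n_enzymes: int = 80,
    edges_per_enzyme: tuple = (2, 4),
    genes_per_enzyme: tuple = (1, 2),
    seed: int = 0,
):
    """Random bipartite metabolite-enzyme graph for null-calibration studies.

    The packaged toy models yield only a handful of nodes; permutation
    nulls of the reporter statistic need a graph large enough that the
    background standardisation is well estimated.  Every enzyme gets
    distinct synthetic genes and a random set of metabolite neighbours.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    mets = [f"met{i:03d}" for i in range(n_metabolites)]
    for m in mets:
        g.add_node(m, kind="metabolite")
    gene_counter = 0
    for j in range(n_enzymes):
        enz = f"enz{j:03d}"
        n_genes = rng.integers(genes_per_enzyme[0], genes_per_enzyme[1] + 1)
        genes = [f"gene{gene_counter + t:04d}" for t in range(n_genes)]
        gene_counter += n_genes
        g.add_node(enz, kind="enzyme", genes=genes)
        k = rng.integers(edges_per_enzyme[0], edges_per_enzyme[1] + 1)
        for m in rng.choice(mets, size=k, replace=False):
            g.add_edge(enz, m)
    return g


def make_expression_dataset(
    graph,
    planted_metabolites=(),
    effect_p: float = 1e-4,
    seed: int = 0,
) -> ExpressionStats:
    """Expression table with planted differential neighbourhoods.

    Null genes draw p ~ Uniform(0, 1); genes of enzymes adjacent to a
    planted metabolite draw p ~ Uniform(0, effect_p).  Reproducible from
    ``seed``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    planted_enzymes = set()
    for met in planted_metabolites:
        if met not in graph:
            raise KeyError(f"planted metabolite {met!r} not in graph")
        planted_enzymes.update(graph.neighbors(met))
    genes: dict = {}
    for node, attrs in sorted(graph.nodes(data=True)):
        if attrs.get("kind") == "enzyme":
            for g in attrs["genes"]:
                genes[g] = genes.get(g, False) or node in planted_enzymes
    rows = []
    for g, planted in sorted(genes.items()):
        hi = effect_p if planted else 1.0
        p = rng.uniform(0.0, hi)
        rows.append({"gene_id": g, "pvalue": max(p, 1e-300)})
    return ExpressionStats(pd.DataFrame(rows))
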