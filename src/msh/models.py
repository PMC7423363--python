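"""Species-level stoichiometric models and their on-disk formats.

A :class:`StoichiometricModel` is the minimal container needed for
flux-balance analysis of one community member: the stoichiometric matrix
``A`` (metabolites x reactions), flux bounds in mmol/gCDW/h, a biomass
objective, an exchange map naming which reaction exchanges each externally
tracked metabolite, and gene-reaction links for reporter-metabolite
analysis.

Two formats are supported: SBML (FBC conventions, read and written through
cobrapy) and a small versioned JSON dialect documented in
``docs/model_format.md``.  The packaged toy aerobe/anaerobe models use the
JSON dialect; curated genome-scale models can be supplied as SBML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

JSON_FORMAT_TAG = "msh-model/1"


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending element."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


@dataclass
class StoichiometricModel:
    """A species-level metabolic network for FBA.

    Parameters
    ----------
    model_id : str
        Identifier of the model/species.
    metabolites : list of str
        Ordered metabolite IDs (one row of ``S`` each), compartment-suffixed.
    reactions : list of str
        Ordered reaction IDs (one column of ``S`` each).
    S : scipy.sparse matrix
        Stoichiometric coefficients, metabolites x reactions.
    lower_bounds, upper_bounds : ndarray
        Per-reaction flux bounds, mmol/gCDW/h.
    objective : ndarray
        Cost vector ``c``; exactly one nonzero entry (the biomass reaction).
    exchange_map : dict
        Metabolite ID -> exchange reaction ID for externally tracked
        metabolites.  Sign convention: exchange flux > 0 secretes into the
        environment, < 0 takes up.
    gene_reaction_links : dict
        Reaction ID -> list of associated gene IDs.
    compartments : dict
        Metabolite ID -> compartment tag.
    carbon : dict
        Metabolite ID -> carbon atoms per molecule (used for carbon audits).
    """

    model_id: str
    metabolites: list
    reactions: list
    S: sp.spmatrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective: np.ndarray
    exchange_map: dict = field(default_factory=dict)
    gene_reaction_links: dict = field(default_factory=dict)
    compartments: dict = field(default_factory=dict)
    carbon: dict = field(default_factory=dict)

    def __post_init__(self):
        self.S = sp.csr_matrix(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        self._rxn_index = {r: j for j, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    @property
    def biomass_reaction(self) -> str:
        (j,) = np.flatnonzero(self.objective)
        return self.reactions[j]

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ModelValidationError(
                f"{self.model_id}: S is {m}x{n} but model lists "
                f"{len(self.metabolites)} metabolites and {len(self.reactions)} reactions"
            )
        if len(self.lower_bounds) != n or len(self.upper_bounds) != n:
            raise ModelValidationError(f"{self.model_id}: bound vectors must have length {n}")
        bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)
        if bad.size:
            raise ModelValidationError(
                f"{self.model_id}: lower bound exceeds upper bound for reaction "
                f"{self.reactions[bad[0]]!r}"
            )
        nz = np.flatnonzero(self.objective)
        if nz.size != 1:
            raise ModelValidationError(
                f"{self.model_id}: expected exactly one objective (biomass) reaction, "
                f"found {nz.size}"
            )
        for met, rxn in self.exchange_map.items():
            if rxn not in self._rxn_index:
                raise ModelValidationError(
                    f"{self.model_id}: exchange_map names unknown reaction {rxn!r} for {met!r}"
                )
            if met not in self._met_index:
                raise ModelValidationError(
                    f"{self.model_id}: exchange_map names unknown metabolite {met!r}"
                )
        for rxn in self.gene_reaction_links:
            if rxn not in self._rxn_index:
                raise ModelValidationError(
                    f"{self.model_id}: gene link names unknown reaction {rxn!r}"
                )

    def dense_stoichiometry(self) -> np.ndarray:
        """Dense ``S`` with rows/columns sorted by ID (for format comparisons)."""
        rows = np.argsort(self.metabolites)
        cols = np.argsort(self.reactions)
        return np.asarray(self.S.todense())[np.ix_(rows, cols)]

    # -- JSON dialect ------------------------------------------------------
    def to_json_dict(self) -> dict:
        rxns = []
        for j, rid in enumerate(self.reactions):
            col = self.S.getcol(j).tocoo()
            stoich = {self.metabolites[i]: float(v) for i, v in zip(col.row, col.data)}
            rxns.append(
                {
                    "id": rid,
                    "stoichiometry": stoich,
                    "lower_bound": float(self.lower_bounds[j]),
                    "upper_bound": float(self.upper_bounds[j]),
                    "genes": list(self.gene_reaction_links.get(rid, [])),
                }
            )
        mets = [
            {
                "id": m,
                "compartment": self.compartments.get(m, "c"),
                "carbon": float(self.carbon.get(m, 0.0)),
            }
            for m in self.metabolites
        ]
        return {
            "format": JSON_FORMAT_TAG,
            "id": self.model_id,
            "metabolites": mets,
            "reactions": rxns,
            "objective": self.biomass_reaction,
            "exchanges": dict(self.exchange_map),
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def from_json_dict(cls, doc: dict) -> "StoichiometricModel":
        if not isinstance(doc, dict) or doc.get("format") != JSON_FORMAT_TAG:
            raise ModelParseError(
                f"missing or unsupported 'format' tag (expected {JSON_FORMAT_TAG!r})"
            )
        try:
            mets = [m["id"] for m in doc["metabolites"]]
            comp = {m["id"]: m.get("compartment", "c") for m in doc["metabolites"]}
            carbon = {m["id"]: float(m.get("carbon", 0.0)) for m in doc["metabolites"]}
            rxn_ids, lbs, ubs, genes = [], [], [], {}
            midx = {m: i for i, m in enumerate(mets)}
            rows, cols, vals = [], [], []
            for j, r in enumerate(doc["reactions"]):
                rxn_ids.append(r["id"])
                lbs.append(float(r["lower_bound"]))
                ubs.append(float(r["upper_bound"]))
                if r.get("genes"):
                    genes[r["id"]] = list(r["genes"])
                for met, v in r["stoichiometry"].items():
                    if met not in midx:
                        raise ModelParseError(
                            f"reaction {r['id']!r} references unknown metabolite {met!r}"
                        )
                    rows.append(midx[met])
                    cols.append(j)
                    vals.append(float(v))
            objective_rxn = doc["objective"]
        except KeyError as exc:
            raise ModelParseError(f"missing required element {exc.args[0]!r}") from exc
        c = np.zeros(len(rxn_ids))
        if objective_rxn not in rxn_ids:
            raise ModelValidationError(
                f"objective reaction {objective_rxn!r} is not in the reaction list"
            )
        c[rxn_ids.index(objective_rxn)] = 1.0
        S = sp.coo_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_ids)))
        return cls(
            model_id=doc.get("id", "model"),
            metabolites=mets,
            reactions=rxn_ids,
            S=S,
            lower_bounds=np.array(lbs),
            upper_bounds=np.array(ubs),
            objective=c,
            exchange_map=dict(doc.get("exchanges", {})),
            gene_reaction_links=genes,
            compartments=comp,
            carbon=carbon,
        )

    # -- cobra / SBML bridge ----------------------------------------------
    @classmethod
    def from_cobra(cls, cm) -> "StoichiometricModel":
        mets = [m.id for m in cm.metabolites]
        rxns = [r.id for r in cm.reactions]
        midx = {m: i for i, m in enumerate(mets)}
        rows, cols, vals = [], [], []
        lbs, ubs = [], []
        genes = {}
        c = np.zeros(len(rxns))
        for j, r in enumerate(cm.reactions):
            lbs.append(r.lower_bound)
            ubs.append(r.upper_bound)
            if r.objective_coefficient:
                c[j] = r.objective_coefficient
            if r.genes:
                genes[r.id] = sorted(g.id for g in r.genes)
            for met, v in r.metabolites.items():
                rows.append(midx[met.id])
                cols.append(j)
                vals.append(float(v))
        exchange_map = {}
        for r in cm.exchanges:
            if len(r.metabolites) == 1:
                (met,) = r.metabolites
                exchange_map[met.id] = r.id
        carbon = {}
        comp = {}
        for m in cm.metabolites:
            comp[m.id] = m.compartment or "c"
            try:
                carbon[m.id] = float(m.elements.get("C", 0))
            except Exception:
                carbon[m.id] = 0.0
        S = sp.coo_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))
        return cls(
            model_id=cm.id or "model",
            metabolites=mets,
            reactions=rxns,
            S=S,
            lower_bounds=np.array(lbs),
            upper_bounds=np.array(ubs),
            objective=c,
            exchange_map=exchange_map,
            gene_reaction_links=genes,
            compartments=comp,
            carbon=carbon,
        )

    def to_cobra(self):
        import cobra

        cm = cobra.Model(self.model_id)
        comps = sorted(set(self.compartments.values()) or {"c"})
        cm.compartments = {k: k for k in comps}
        cmets = {}
        for m in self.metabolites:
            nC = int(round(self.carbon.get(m, 0.0)))
            met = cobra.Metabolite(
                m,
                compartment=self.compartments.get(m, "c"),
                formula=f"C{nC}" if nC else "",
            )
            cmets[m] = met
        cm.add_metabolites(list(cmets.values()))
        crxns = []
        for j, rid in enumerate(self.reactions):
            r = cobra.Reaction(rid)
            r.lower_bound = float(self.lower_bounds[j])
            r.upper_bound = float(self.upper_bounds[j])
            crxns.append(r)
        cm.add_reactions(crxns)
        for j, rid in enumerate(self.reactions):
            col = self.S.getcol(j).tocoo()
            cm.reactions.get_by_id(rid).add_metabolites(
                {cmets[self.metabolites[i]]: float(v) for i, v in zip(col.row, col.data)}
            )
            if rid in self.gene_reaction_links:
                cm.reactions.get_by_id(rid).gene_reaction_rule = " or ".join(
                    self.gene_reaction_links[rid]
                )
        cm.objective = self.biomass_reaction
        # SBML round-trips exchanges by the boundary convention; keep IDs stable
        return cm

    def write_sbml(self, path) -> None:
        import cobra.io

        cobra.io.write_sbml_model(self.to_cobra(), str(path))


def load_model(path, format: str | None = None) -> StoichiometricModel:
    """Load a :class:`StoichiometricModel` from ``path``.

    Parameters
    ----------
    path : path-like
        Model file.
    format : {"sbml", "json", None}
        File format; inferred from the suffix when ``None``.

    Raises
    ------
    ModelParseError
        If the file cannot be parsed in the named format.
    ModelValidationError
        If the parsed model violates a structural invariant (e.g. missing
        biomass objective, lb > ub).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path.name}: invalid JSON at line {exc.lineno}") from exc
        return StoichiometricModel.from_json_dict(doc)
    if format == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:
            raise ModelParseError(f"{path.name}: SBML parse failed: {exc}") from exc
        model = StoichiometricModel.from_cobra(cm)
        if not np.any(model.objective):
            raise ModelValidationError(f"{path.name}: SBML model has no biomass objective")
        return model
    raise ValueError(f"unknown model format {format!r}")
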