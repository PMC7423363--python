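"""Flux-balance analysis with kinetic uptake bounds.

Each species' growth rate and exchange fluxes come from the linear program

    max  c.v    s.t.  A v = 0,   lb <= v <= ub

where the uptake bound of each externally tracked metabolite is the
Michaelis-Menten rate ``v_max * S / (K_m + S)`` evaluated at the current
environmental concentration.  Alternate optima are resolved parsimoniously:
a second LP minimises total absolute flux at the optimal growth rate, so
exchange fluxes are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _lp
from .models import StoichiometricModel

#: kinetic defaults for metabolites without an explicit entry (mmol/gCDW/h, mM)
DEFAULT_V_MAX = 10.0
DEFAULT_K_M = 0.01


class FBAError(RuntimeError):
    pass


def uptake_bound(v_max: float, K_m: float, concentration: float) -> float:
    """Michaelis-Menten uptake bound ``v_max * S / (K_m + S)``.

    Parameters are the transporter capacity ``v_max`` (mmol/gCDW/h), the
    half-saturation constant ``K_m`` (mM) and the extracellular
    concentration ``S`` (mM).  Strictly increasing in ``S`` and bounded
    above by ``v_max``.
    """
    if v_max < 0:
        raise ValueError("v_max must be >= 0")
    if K_m <= 0:
        raise ValueError("K_m must be > 0")
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration!r}")
    return v_max * concentration / (K_m + concentration)


@dataclass
class KineticEntry:
    v_max: float = DEFAULT_V_MAX
    K_m: float = DEFAULT_K_M

    def bound(self, concentration: float) -> float:
        return uptake_bound(self.v_max, self.K_m, concentration)


@dataclass
class KineticParams:
    """Per-(species, metabolite) Michaelis-Menten parameters.

    Metabolites without an explicit entry fall back to the defaults
    (v_max = 10 mmol/gCDW/h, K_m = 0.01 mM).
    """

    entries: dict = field(default_factory=dict)  # (species, met) -> KineticEntry
    default: KineticEntry = field(default_factory=KineticEntry)

    def set(self, species: str, metabolite: str, v_max: float, K_m: float) -> None:
        if v_max < 0 or K_m <= 0:
            raise ValueError("require v_max >= 0 and K_m > 0")
        self.entries[(species, metabolite)] = KineticEntry(v_max, K_m)

    def get(self, species: str, metabolite: str) -> KineticEntry:
        return self.entries.get((species, metabolite), self.default)

    def bound(self, species: str, metabolite: str, concentration: float) -> float:
        return self.get(species, metabolite).bound(concentration)


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``mu`` is the biomass growth rate (1/h); ``fluxes`` the full flux vector
    (mmol/gCDW/h); ``exchange`` the exchange fluxes of tracked metabolites
    (positive = secretion into the environment, negative = uptake);
    ``status`` one of ``optimal``/``infeasible``.
    """

    status: str
    mu: float
    fluxes: np.ndarray | None = None
    exchange: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == _lp.OPTIMAL


class FBAProblem:
    """Persistent FBA (+ parsimonious tie-break) LPs for one model.

    Reusing the underlying solver state makes repeated solves with varying
    uptake bounds cheap, which the dynamic community simulation relies on.
    """

    def __init__(self, model: StoichiometricModel, backend: str = "auto"):
        self.model = model
        m, n = model.S.shape
        self._lp1 = _lp.make_lp(model.S, model.objective, maximize=True, backend=backend)
        # pFBA stage: variables (v+, v-), minimise sum, subject to
        # A(v+ - v-) = 0 and c.(v+ - v-) >= mu* (row m, updated per solve).
        A2 = sp.vstack([model.S, sp.csr_matrix(model.objective)])
        A2 = sp.hstack([A2, -A2]).tocsr()
        self._lp2 = _lp.make_lp(A2, np.ones(2 * n), maximize=False, backend=backend)
        self._growth_row = m
        self._n = n
        self._ex_idx = {met: model.reaction_index(rxn) for met, rxn in model.exchange_map.items()}

    def solve(
        self,
        dynamic_bounds: dict | None = None,
        parsimonious: bool = True,
    ) -> FluxSolution:
        """Solve FBA with per-metabolite uptake bounds overriding model bounds.

        ``dynamic_bounds`` maps metabolite ID -> maximum uptake rate
        (mmol/gCDW/h, >= 0); the exchange lower bound becomes ``-bound``
        (tightened only, never relaxed beyond the model file's bound).
        """
        model = self.model
        lb = model.lower_bounds.copy()
        ub = model.upper_bounds.copy()
        if dynamic_bounds:
            for met, bound in dynamic_bounds.items():
                if met not in self._ex_idx:
                    raise KeyError(f"{met!r} has no exchange reaction in {model.model_id}")
                if not np.isfinite(bound):
                    raise ValueError(f"non-finite uptake bound for {met!r}")
                j = self._ex_idx[met]
                lb[j] = max(model.lower_bounds[j], -float(bound))
                if lb[j] > ub[j]:  # model forbids uptake; keep consistent
                    lb[j] = ub[j]
        status, obj, x = self._lp1.solve(lb, ub)
        if status == _lp.UNBOUNDED:
            raise FBAError(f"{model.model_id}: unbounded objective (missing constraints)")
        if status == _lp.FAILED:
            raise FBAError(f"{model.model_id}: LP solver failure")
        if status == _lp.INFEASIBLE:
            return FluxSolution(status=_lp.INFEASIBLE, mu=np.nan)
        mu = float(obj)
        v = x
        if parsimonious and mu > 0:
            n = self._n
            lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
            ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
            self._lp2.set_row_lower(self._growth_row, mu * (1 - 1e-9) - 1e-12)
            s2, _, x2 = self._lp2.solve(lb2, ub2)
            if s2 == _lp.OPTIMAL:
                v = x2[:n] - x2[n:]
        exchange = {met: float(v[j]) for met, j in self._ex_idx.items()}
        return FluxSolution(status=_lp.OPTIMAL, mu=mu, fluxes=v, exchange=exchange)


def solve_fba(
    model: StoichiometricModel,
    dynamic_bounds: dict | None = None,
    parsimonious: bool = True,
    backend: str = "auto",
) -> FluxSolution:
    """One-shot FBA solve; see :class:`FBAProblem` for the loop-friendly form."""
    return FBAProblem(model, backend=backend).solve(dynamic_bounds, parsimonious)
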