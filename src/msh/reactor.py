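"""Two-species chemostat (CSTR) dynamics driven by per-step FBA.

The community is simulated with the dynamic multispecies metabolic
modelling (DMMM) scheme: at every step of length ``dt`` each species'
growth rate and exchange fluxes are obtained by FBA with Michaelis-Menten
uptake bounds evaluated at the current extracellular concentrations, and
the extracellular state is advanced with the analytical update

    X_f  = X_0 * exp((mu - F/V) * dt)
    S_f  = S_0 + sum_i v_ij*V/(mu_i*V - F) * (X_0i*exp((mu_i - F/V)dt) - X_0i)
               + F*(S_feed - S_0)/V * dt

Dissolved oxygen receives gas-liquid transfer ``kLa (S* - S)`` instead of
feed dilution.  The obligate anaerobe is gated on dissolved oxygen: above
the growth threshold (350 nM by default) its FBA is skipped and its growth
rate and fluxes are zero for the step.

Oxygen handling
---------------
The dissolved O2 pool in the modelled reactor turns over in ~1e-4 h
(supply of order 1 mmol/L/h against a pool of order 1e-5 mM near the
anaerobe's gate), i.e. oxygen equilibrates within seconds while ``dt`` is
tens of seconds.  The default ``oxygen_mode="quasi_steady"`` therefore
closes each step by solving the algebraic balance

    kLa (S* - S) = sum_i X_i * min(demand_i, MM_i(S))

for the dissolved concentration.  ``oxygen_mode="explicit"`` applies the
discrete update literally (one transfer/consumption step per ``dt``,
floored at zero with clamp events logged); it is accurate only when
``dt * (kLa + X v_max / K_m)`` is small, which the config validator checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .fba import FBAProblem, KineticParams

OXYGEN = "o2_e"

#: air-saturated dissolved O2 at 37 C and 1 atm, mg/L (probe calibration basis)
AIR_SATURATION_MG_L = 6.056
#: mole fraction of O2 in air
AIR_O2_FRACTION = 0.2095
O2_MOLAR_MASS = 32.0  # g/mol


def residence_time_h(volume_ml: float, flow_ml_h: float) -> float:
    """Reactor residence time V/F in hours (200 ml at 40 ml/h -> 5 h)."""
    if volume_ml <= 0 or flow_ml_h <= 0:
        raise ValueError("volume and flow must be positive")
    return volume_ml / flow_ml_h


def sparge_fraction(o2_ml_min: float, total_gas_ml_min: float) -> float:
    """O2 fraction of the gas feed (1.7 of 50 ml/min -> 0.034)."""
    if total_gas_ml_min <= 0 or o2_ml_min < 0 or o2_ml_min > total_gas_ml_min:
        raise ValueError("require 0 <= o2 flow <= total gas flow")
    return o2_ml_min / total_gas_ml_min


def o2_saturation_uM(
    fraction: float,
    air_mg_per_l: float = AIR_SATURATION_MG_L,
    air_o2_fraction: float = AIR_O2_FRACTION,
) -> float:
    """Dissolved-O2 saturation (uM) for a gas feed with the given O2 fraction.

    Henry's law scaling of the air-saturated reference: 6.056 mg/L at 37 C
    corresponds to air (20.95% O2), so a 3.4% O2 sparge saturates at
    ``6.056/32 * 1000 * 0.034/0.2095 = 30.714`` uM.
    """
    if fraction < 0:
        raise ValueError("O2 fraction must be >= 0")
    air_uM = air_mg_per_l / O2_MOLAR_MASS * 1000.0
    return air_uM * fraction / air_o2_fraction


@dataclass
class ReactorConfig:
    """CSTR configuration.

    Volumes in liters, flows in liters/h, concentrations in mM, times in
    hours.  ``s_star_mM`` (dissolved O2 saturation) is derived from the
    sparge composition unless set explicitly.
    """

    volume_L: float = 0.2
    flow_L_h: float = 0.04  # F_in = F_out (constant volume)
    s_feed: dict = field(default_factory=dict)  # metabolite -> mM
    kla_per_h: float = 42.0
    o2_inflow_ml_min: float = 1.7
    total_gas_ml_min: float = 50.0
    s_star_mM: float | None = None
    dt_h: float = 0.01
    o2_growth_threshold_nM: float = 350.0
    dextran_glucose_units: int = 100
    dextran_release_fraction: float = 0.5
    oxygen_mode: str = "quasi_steady"  # or "explicit"
    o2_dilution: bool = False  # optional F/V dilution term in the O2 update
    exhaustion_cap: bool = True  # cap uptake bounds by per-step availability
    extinction_floor: float = 1e-9  # g/L, reporting floor (never hard-zeroed)
    classification_floor: float = 1e-3  # g/L, state-label floor

    def __post_init__(self):
        if self.volume_L <= 0:
            raise ValueError("volume must be positive")
        if self.flow_L_h < 0:
            raise ValueError("flow must be >= 0")
        if self.dt_h <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.dextran_release_fraction <= 1.0:
            raise ValueError("dextran release fraction must be in [0, 1]")
        if self.oxygen_mode not in ("quasi_steady", "explicit"):
            raise ValueError(f"unknown oxygen_mode {self.oxygen_mode!r}")

    @property
    def dilution_rate(self) -> float:
        """D = F/V, 1/h."""
        return self.flow_L_h / self.volume_L

    @property
    def residence_time(self) -> float:
        return residence_time_h(self.volume_L * 1000.0, self.flow_L_h * 1000.0)

    @property
    def s_star(self) -> float:
        """Dissolved O2 saturation in mM."""
        if self.s_star_mM is not None:
            return self.s_star_mM
        frac = sparge_fraction(self.o2_inflow_ml_min, self.total_gas_ml_min)
        return o2_saturation_uM(frac) / 1000.0

    @property
    def o2_threshold_mM(self) -> float:
        return self.o2_growth_threshold_nM * 1e-6

    def with_oxygen_inflow(self, ml_min: float) -> "ReactorConfig":
        return replace(self, o2_inflow_ml_min=ml_min, s_star_mM=None)

    def with_feed(self, metabolite: str, mM: float) -> "ReactorConfig":
        feed = dict(self.s_feed)
        feed[metabolite] = mM
        return replace(self, s_feed=feed)

    def explicit_o2_stability(self, biomass_g_L: float, v_max: float, K_m: float) -> float:
        """Stability number for explicit O2 stepping; should be << 1."""
        return self.dt_h * (self.kla_per_h + biomass_g_L * v_max / K_m)

    @classmethod
    def from_yaml(cls, path) -> "ReactorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {
            k: v
            for k, v in self.__dict__.items()
            if not k.startswith("_")
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ReactorState:
    """Instantaneous reactor contents: biomasses (g/L), metabolites and
    dissolved O2 (mM), time (h)."""

    t: float
    biomass: dict
    metabolites: dict
    oxygen: float

    def __post_init__(self):
        for sp, x in self.biomass.items():
            if x < 0:
                raise ValueError(f"negative biomass for {sp!r}")
        for met, s in self.metabolites.items():
            if s < 0:
                raise ValueError(f"negative concentration for {met!r}")
        if self.oxygen < 0:
            raise ValueError("negative dissolved oxygen")

    def copy(self) -> "ReactorState":
        return ReactorState(
            self.t, dict(self.biomass), dict(self.metabolites), self.oxygen
        )


# ---------------------------------------------------------------------------
# analytical stepping


def step_biomass(x0: float, mu: float, config: ReactorConfig, dt: float | None = None) -> float:
    """Biomass update ``X0 * exp((mu - F/V) dt)`` (exact for constant mu)."""
    if x0 < 0:
        raise ValueError("biomass must be >= 0")
    dt = config.dt_h if dt is None else dt
    return x0 * math.exp((mu - config.dilution_rate) * dt)


def _consumption_term(contributions, D: float, dt: float) -> float:
    """Sum_i v_ij*V/(mu_i*V - F) * (X0_i e^((mu_i - D)dt) - X0_i), in mM.

    Equivalently v_ij/(mu_i - D) * X0_i (e^((mu_i - D)dt) - 1); switches to
    the analytic limit ``v_ij X0_i dt`` when mu_i ~= D.
    """
    total = 0.0
    for v, x0, mu in contributions:
        if x0 == 0.0 or v == 0.0:
            continue
        g = mu - D
        if abs(g) < 1e-9:
            total += v * x0 * dt
        else:
            total += v / g * x0 * (math.exp(g * dt) - 1.0)
    return total


def step_metabolite(
    s0: float,
    contributions,
    config: ReactorConfig,
    feed_S: float = 0.0,
    dt: float | None = None,
) -> float:
    """Metabolite update: biological exchange + feed dilution, floored at 0.

    ``contributions`` is an iterable of ``(v_ij, X0_i, mu_i)`` with the
    secretion-positive sign convention.
    """
    dt = config.dt_h if dt is None else dt
    D = config.dilution_rate
    s = s0 + _consumption_term(contributions, D, dt) + D * (feed_S - s0) * dt
    return max(s, 0.0)


def step_oxygen(
    s0: float,
    contributions,
    config: ReactorConfig,
    dt: float | None = None,
) -> float:
    """Explicit dissolved-O2 update: biological exchange plus
    ``kLa (S* - S0) dt``; no feed/outflow dilution term (the gas phase, not
    the liquid feed, carries oxygen).  Floored at 0."""
    dt = config.dt_h if dt is None else dt
    D = config.dilution_rate
    s = s0 + _consumption_term(contributions, D, dt) + config.kla_per_h * (config.s_star - s0) * dt
    if config.o2_dilution:
        s -= D * s0 * dt
    return max(s, 0.0)


def oxygen_quasi_steady(consumers, config: ReactorConfig) -> float:
    """Quasi-steady dissolved O2: solve ``kLa (S* - S) = sum_i X_i *
    min(demand_i, MM_i(S))`` for S in [0, S*].

    ``consumers`` is an iterable of ``(X_i, demand_i, v_max_i, K_m_i)``
    where ``demand_i`` is the specific O2 uptake the species' FBA asked for
    (mmol/gCDW/h, magnitude).
    """
    s_star = config.s_star
    kla = config.kla_per_h
    consumers = [c for c in consumers if c[0] > 0 and c[1] > 0]
    if not consumers or s_star <= 0:
        return s_star

    def balance(s):
        demand = 0.0
        for x, d, vmax, km in consumers:
            demand += x * min(d, vmax * s / (km + s))
        return kla * (s_star - s) - demand

    if balance(s_star) >= 0:
        return s_star
    return brentq(balance, 0.0, s_star, xtol=1e-15, rtol=1e-12)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Time-ordered reactor states with per-step growth rates and exchange
    fluxes, plus a log of gate/clamp/infeasibility events."""

    species: list
    tracked: list
    times: np.ndarray
    biomass: dict  # species -> array
    metabolites: dict  # met -> array
    oxygen: np.ndarray
    mu: dict  # species -> array
    exchange: dict  # (species, met) -> array
    events: list = field(default_factory=list)

    @property
    def final_state(self) -> ReactorState:
        return ReactorState(
            t=float(self.times[-1]),
            biomass={sp: float(self.biomass[sp][-1]) for sp in self.species},
            metabolites={m: float(self.metabolites[m][-1]) for m in self.tracked},
            oxygen=float(self.oxygen[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, variable, value."""
        parts = []
        for sp in self.species:
            parts.append(pd.DataFrame({"time_h": self.times, "variable": f"X[{sp}]", "value": self.biomass[sp]}))
            parts.append(pd.DataFrame({"time_h": self.times, "variable": f"mu[{sp}]", "value": self.mu[sp]}))
        for m in self.tracked:
            parts.append(pd.DataFrame({"time_h": self.times, "variable": f"S[{m}]", "value": self.metabolites[m]}))
        parts.append(pd.DataFrame({"time_h": self.times, "variable": "S[o2]", "value": self.oxygen}))
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_events(self, path) -> None:
        """Run log: one line per gate/clamp/infeasibility event."""
        with open(path, "w") as fh:
            fh.write("event\ttime_h\tsubject\tdetail\n")
            for kind, t, subject, detail in self.events:
                fh.write(f"{kind}\t{t:.4f}\t{subject}\t{detail}\n")

    def window_mean_biomass(self, species: str, t0: float, t1: float) -> float:
        mask = (self.times >= t0) & (self.times <= t1)
        return float(np.mean(self.biomass[species][mask]))

    def carbon_audit(self, models: dict, biomass_carbon: float = 40.0) -> dict:
        """Steady-state carbon bookkeeping (mmol C / L / h at the final state).

        Inflow carries feed metabolites; outflow carries residual
        metabolites and biomass (``biomass_carbon`` mmol C per gCDW).
        Respired CO2 leaves through the gas phase, so inflow >= outflow and
        the discrepancy estimates respiration plus numerical error.
        """
        state = self.final_state
        carbon = {}
        for m in models.values():
            carbon.update(m.carbon)
        D = self._config_D
        c_in = sum(D * s * carbon.get(met, 0.0) for met, s in self._feed.items())
        c_out = sum(D * s * carbon.get(met, 0.0) for met, s in state.metabolites.items())
        c_out += sum(D * x * biomass_carbon for x in state.biomass.values())
        return {"carbon_in": c_in, "carbon_out": c_out, "discrepancy": c_in - c_out}


def simulate(
    models: dict,
    kinetics: KineticParams,
    config: ReactorConfig,
    init: ReactorState,
    duration: float,
    record_every: int = 1,
    gated_species: set | None = None,
    problems: dict | None = None,
) -> Trajectory:
    """Simulate the community for ``duration`` hours.

    Per step: (1) Michaelis-Menten uptake bounds from the current
    concentrations (optionally capped by per-step availability);
    (2) the anaerobe O2 gate -- above the threshold its FBA is skipped and
    its growth rate and fluxes are zero; (3) per-species FBA with
    parsimonious tie-break; (4) the analytical biomass/metabolite updates
    and the dissolved-O2 closure.

    ``gated_species`` defaults to every species whose model has no O2
    exchange (obligate anaerobes).  An infeasible FBA zeroes that species'
    rates for the step and logs an event.  Pass ``problems`` to reuse
    persistent LP objects across calls.
    """
    if duration < config.dt_h:
        raise ValueError("duration must be at least one step")
    dt = config.dt_h
    D = config.dilution_rate
    species = list(models)
    if gated_species is None:
        gated_species = {sp for sp, m in models.items() if OXYGEN not in m.exchange_map}
    tracked = sorted(
        {met for m in models.values() for met in m.exchange_map if met != OXYGEN}
    )
    if problems is None:
        problems = {}
    for sp_name, m in models.items():
        problems.setdefault(sp_name, FBAProblem(m))

    X = {sp: float(init.biomass.get(sp, 0.0)) for sp in species}
    S = {met: float(init.metabolites.get(met, 0.0)) for met in tracked}
    s_o2 = float(init.oxygen)
    threshold = config.o2_threshold_mM

    n_steps = int(round(duration / dt))
    rec_t, rec_o2 = [], []
    rec_X = {sp: [] for sp in species}
    rec_S = {m: [] for m in tracked}
    rec_mu = {sp: [] for sp in species}
    rec_ex = {(sp, m): [] for sp in species for m in tracked}
    events: list = []

    def record(t, mu, ex):
        rec_t.append(t)
        rec_o2.append(s_o2)
        for sp in species:
            rec_X[sp].append(X[sp])
            rec_mu[sp].append(mu.get(sp, 0.0))
        for m in tracked:
            rec_S[m].append(S[m])
            for sp in species:
                rec_ex[(sp, m)].append(ex.get(sp, {}).get(m, 0.0))

    record(init.t, {}, {})

    t = init.t
    for step in range(n_steps):
        mu = {}
        ex = {}
        o2_demand = {}
        for sp_name in species:
            model = models[sp_name]
            if sp_name in gated_species and s_o2 > threshold:
                mu[sp_name] = 0.0
                ex[sp_name] = {}
                events.append(("gate", t, sp_name, s_o2))
                continue
            bounds = {}
            for met in model.exchange_map:
                if met == OXYGEN:
                    bounds[met] = kinetics.bound(sp_name, met, s_o2)
                elif met in S:
                    b = kinetics.bound(sp_name, met, S[met])
                    if config.exhaustion_cap and X[sp_name] > 0:
                        b = min(b, S[met] / (X[sp_name] * dt))
                    bounds[met] = b
            sol = problems[sp_name].solve(bounds)
            if not sol.ok:
                events.append(("infeasible", t, sp_name, sol.status))
                mu[sp_name] = 0.0
                ex[sp_name] = {}
                continue
            mu[sp_name] = sol.mu
            ex[sp_name] = sol.exchange
            o2_demand[sp_name] = max(0.0, -sol.exchange.get(OXYGEN, 0.0))

        # metabolite balances, then biomass, then the oxygen closure
        new_S = {}
        for met in tracked:
            contribs = [(ex[sp].get(met, 0.0), X[sp], mu[sp]) for sp in species]
            raw = S[met] + _consumption_term(contribs, D, dt) + D * (
                config.s_feed.get(met, 0.0) - S[met]
            ) * dt
            if raw < -1e-12:
                events.append(("clamp", t, met, raw))
            new_S[met] = max(raw, 0.0)

        if config.oxygen_mode == "quasi_steady":
            consumers = []
            for sp_name, d in o2_demand.items():
                entry = kinetics.get(sp_name, OXYGEN)
                consumers.append((X[sp_name], d, entry.v_max, entry.K_m))
            new_o2 = oxygen_quasi_steady(consumers, config)
        else:
            contribs = [(ex[sp].get(OXYGEN, 0.0), X[sp], mu[sp]) for sp in species]
            raw = s_o2 + _consumption_term(contribs, D, dt) + config.kla_per_h * (
                config.s_star - s_o2
            ) * dt
            if config.o2_dilution:
                raw -= D * s_o2 * dt
            if raw < -1e-12:
                events.append(("clamp", t, OXYGEN, raw))
            new_o2 = max(raw, 0.0)

        for sp_name in species:
            X[sp_name] = X[sp_name] * math.exp((mu[sp_name] - D) * dt)

        S = new_S
        s_o2 = new_o2
        t = init.t + (step + 1) * dt

        for val in list(X.values()) + list(S.values()) + [s_o2]:
            if not np.isfinite(val) or val < 0:
                raise RuntimeError(f"non-finite or negative state at t={t:.3f} h")

        if (step + 1) % record_every == 0 or step == n_steps - 1:
            record(t, mu, ex)

    traj = Trajectory(
        species=species,
        tracked=tracked,
        times=np.asarray(rec_t),
        biomass={sp: np.asarray(v) for sp, v in rec_X.items()},
        metabolites={m: np.asarray(v) for m, v in rec_S.items()},
        oxygen=np.asarray(rec_o2),
        mu={sp: np.asarray(v) for sp, v in rec_mu.items()},
        exchange={k: np.asarray(v) for k, v in rec_ex.items()},
        events=events,
    )
    traj._config_D = D
    traj._feed = dict(config.s_feed)
    return traj
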