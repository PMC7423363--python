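"""Forward/reverse sweep protocol, steady-state classification and the
bistability/hysteresis map.

A sweep walks an input parameter (glucose feed concentration or oxygen
sparge rate) along a grid, running the community to steady state at each
condition and carrying the final state over as the next condition's
initial state.  The community is classified at each condition as
``aerobe_only``, ``aerobe_anaerobe`` or ``washout``; the first grid value
at which the label changes is the tipping point.  A condition is bistable
when the forward and reverse passes disagree, and the hysteresis ratio is
the reverse/forward ratio of the aerobe's steady biomass (~1 in monostable
regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import FBAProblem, KineticParams
from .reactor import OXYGEN, ReactorConfig, ReactorState, simulate

GLUCOSE = "glc_e"
AEROBE = "aerobe"
ANAEROBE = "anaerobe"

#: convergence test: relative change of 5-h window-mean biomass
STEADY_WINDOW_H = 5.0
STEADY_TOL = 5e-4
MIN_SETTLE_H = 15.0


@dataclass
class SweepProtocol:
    """One directional pass of a sweep.

    ``direction="forward"`` is the initial pass (glucose rising, or oxygen
    falling from its highest rate); ``"reverse"`` retraces the grid from
    the forward endpoint.  With ``carryover`` each condition starts from
    the previous condition's final state.  ``reseed`` re-inoculates the
    anaerobe at ``reseed_level`` before each condition if it has washed
    out, mirroring experimental re-inoculation; by default only forward
    passes reseed, so reverse-pass persistence is informative.
    """

    swept_parameter: str  # "glucose_feed" | "oxygen_inflow"
    grid: list
    direction: str = "forward"
    settle_time_h: float = 50.0
    carryover: bool = True
    reseed: bool | None = None
    reseed_level: float = 0.0015
    early_exit: bool = True

    def __post_init__(self):
        if self.swept_parameter not in ("glucose_feed", "oxygen_inflow"):
            raise ValueError(f"unknown swept parameter {self.swept_parameter!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.settle_time_h <= 0:
            raise ValueError("settle time must be positive")
        g = np.asarray(self.grid, dtype=float)
        if len(g) < 1 or (len(g) > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0))):
            raise ValueError("grid must be strictly monotone")
        if self.reseed is None:
            self.reseed = self.direction == "forward"


@dataclass
class SweepResult:
    protocol: SweepProtocol
    values: np.ndarray
    labels: list
    biomass: dict  # species -> array of steady biomasses
    final_states: list
    converged: np.ndarray
    floor: float

    @property
    def tipping_points(self) -> list:
        """Grid values at which the state label changes, with the labels."""
        out = []
        for i in range(1, len(self.labels)):
            if self.labels[i] != self.labels[i - 1]:
                out.append((float(self.values[i]), self.labels[i - 1], self.labels[i]))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"value": self.values, "label": self.labels, "converged": self.converged})
        for sp, x in self.biomass.items():
            df[f"X[{sp}]"] = x
        return df


def classify_state(state: ReactorState, floor: float) -> str:
    """Label the community: both species above ``floor`` (g/L) ->
    ``aerobe_anaerobe``; only the aerobe -> ``aerobe_only``; neither ->
    ``washout``."""
    aer = state.biomass.get(AEROBE, 0.0) > floor
    ana = state.biomass.get(ANAEROBE, 0.0) > floor
    if aer and ana:
        return "aerobe_anaerobe"
    if aer:
        return "aerobe_only"
    return "washout"


def default_initial_state(config: ReactorConfig, aerobe_biomass: float = 0.02) -> ReactorState:
    """Paper-style initial condition: the aerobe near its monoculture
    steady state, the anaerobe freshly inoculated at 0.0015 g/L, no free
    glucose, dextran at the feed level, dissolved O2 at saturation."""
    mets = {m: 0.0 for m in config.s_feed}
    if "dex_e" in config.s_feed:
        mets["dex_e"] = config.s_feed["dex_e"]
    return ReactorState(
        t=0.0,
        biomass={AEROBE: aerobe_biomass, ANAEROBE: 0.0015},
        metabolites=mets,
        oxygen=config.s_star,
    )


def _settle(models, kinetics, config, state, protocol, problems):
    """Run one condition to steady state (windowed biomass criterion) or to
    ``settle_time_h``; returns (final_state, converged)."""
    window = STEADY_WINDOW_H
    chunk = window
    elapsed = 0.0
    prev_means = None
    state = state.copy()
    state.t = 0.0
    converged = False
    floor = config.classification_floor
    while elapsed < protocol.settle_time_h - 1e-9:
        span = min(chunk, protocol.settle_time_h - elapsed)
        traj = simulate(
            models, kinetics, config, state, span,
            record_every=max(1, int(round(0.5 / config.dt_h))),
            problems=problems,
        )
        state = traj.final_state
        elapsed += span
        means = {
            sp: traj.window_mean_biomass(sp, state.t - window, state.t)
            for sp in traj.species
        }
        if prev_means is not None and elapsed >= MIN_SETTLE_H:
            ok = True
            for sp, m in means.items():
                if max(m, prev_means[sp]) <= floor:
                    continue  # washed-out species cannot block convergence
                if abs(m - prev_means[sp]) > STEADY_TOL * max(m, prev_means[sp]):
                    ok = False
            if ok:
                converged = True
                if protocol.early_exit:
                    break
        prev_means = means
    return state, converged


def run_sweep(
    protocol: SweepProtocol,
    config: ReactorConfig,
    models: dict,
    kinetics: KineticParams,
    init: ReactorState | None = None,
) -> SweepResult:
    """Execute a sweep pass and classify the steady state at each condition."""
    if init is None:
        init = default_initial_state(config)
    problems = {sp: FBAProblem(m) for sp, m in models.items()}
    state = init.copy()
    floor = config.classification_floor
    values = np.asarray(protocol.grid, dtype=float)
    labels, finals, biomass, conv = [], [], {sp: [] for sp in models}, []
    for value in values:
        if protocol.swept_parameter == "glucose_feed":
            cfg = config.with_feed(GLUCOSE, float(value))
        else:
            cfg = config.with_oxygen_inflow(float(value))
        if not protocol.carryover:
            state = init.copy()
        if protocol.reseed and state.biomass.get(ANAEROBE, 0.0) < protocol.reseed_level:
            state = state.copy()
            state.biomass[ANAEROBE] = protocol.reseed_level
        state, converged = _settle(models, kinetics, cfg, state, protocol, problems)
        labels.append(classify_state(state, floor))
        finals.append(state)
        conv.append(converged)
        for sp in models:
            biomass[sp].append(state.biomass.get(sp, 0.0))
    return SweepResult(
        protocol=protocol,
        values=values,
        labels=labels,
        biomass={sp: np.asarray(v) for sp, v in biomass.items()},
        final_states=finals,
        converged=np.asarray(conv),
        floor=floor,
    )


def hysteresis_ratio(forward: SweepResult, reverse: SweepResult) -> pd.DataFrame:
    """Reverse/forward ratio of the aerobe's steady biomass per condition.

    Grids must cover the same values (the reverse pass retraces the
    forward grid).  Conditions where the forward aerobe biomass is below
    the classification floor get a missing ratio.
    """
    fwd = {float(v): x for v, x in zip(forward.values, forward.biomass[AEROBE])}
    rows = []
    for v, x_rev in zip(reverse.values, reverse.biomass[AEROBE]):
        v = float(v)
        if v not in fwd:
            raise ValueError("forward and reverse grids do not match")
        x_fwd = fwd[v]
        ratio = x_rev / x_fwd if x_fwd > forward.floor else np.nan
        rows.append({"value": v, "aerobe_forward": x_fwd, "aerobe_reverse": x_rev, "ratio": ratio})
    return pd.DataFrame(rows).sort_values("value", ignore_index=True)


def stability_map(
    glucose_mM,
    oxygen_ml_min,
    config: ReactorConfig,
    models: dict,
    kinetics: KineticParams,
    settle_time_h: float = 50.0,
) -> pd.DataFrame:
    """Classify every (glucose, oxygen) condition as monostable or bistable.

    For each glucose concentration the oxygen input runs from its highest
    rate downward (forward pass) and back up (reverse pass), as in the
    sweep protocol; a condition is bistable when the two passes settle in
    different states.  Adds the per-condition hysteresis ratio of the
    aerobe's steady biomass.
    """
    oxy = sorted(float(q) for q in oxygen_ml_min)
    fwd_grid = list(reversed(oxy))  # start oxygen-rich
    rev_grid = oxy
    rows = []
    for g in glucose_mM:
        cfg = config.with_feed(GLUCOSE, float(g))
        fwd = run_sweep(
            SweepProtocol("oxygen_inflow", fwd_grid, "forward", settle_time_h=settle_time_h),
            cfg, models, kinetics,
        )
        rev = run_sweep(
            SweepProtocol("oxygen_inflow", rev_grid, "reverse", settle_time_h=settle_time_h),
            cfg, models, kinetics, init=fwd.final_states[-1],
        )
        ratios = hysteresis_ratio(fwd, rev).set_index("value")["ratio"]
        f_lab = dict(zip(map(float, fwd.values), fwd.labels))
        r_lab = dict(zip(map(float, rev.values), rev.labels))
        for q in oxy:
            a, b = f_lab[q], r_lab[q]
            cls = f"monostable_{a}" if a == b else "bistable"
            rows.append(
                {
                    "glucose_mM": float(g),
                    "oxygen_ml_min": q,
                    "forward_label": a,
                    "reverse_label": b,
                    "stability": cls,
                    "hysteresis_ratio": float(ratios.get(q, np.nan)),
                }
            )
    return pd.DataFrame(rows)
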