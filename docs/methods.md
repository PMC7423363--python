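# Methods

## The model system

The package studies a two-member gut-relevant community in a continuously
stirred tank reactor (CSTR): a facultative aerobe (a *Klebsiella*-like
sugar and short-chain-fatty-acid consumer) and an obligate anaerobe (a
*Bacteroides*-like dextran degrader).  The anaerobe hydrolyses dextran
into glucose, oligosaccharides, acetate and lactate that the aerobe can
use; the aerobe's respiration draws down dissolved oxygen, which the
anaerobe requires to be nearly absent.  This mutual feedback admits two
stable community states under identical inputs — aerobe-only and
aerobe+anaerobe — with hysteresis: which state is reached depends on the
history of glucose and oxygen inputs, not just their current values.

## Dynamic multispecies FBA

The reactor follows the dynamic multispecies metabolic modelling scheme:
at each step of length `dt` every species' growth rate `mu_i` and
exchange fluxes `v_ij` (mmol/gCDW/h; secretion positive) come from a
species-level flux balance analysis

    max c.v   s.t.  A v = 0,  lb <= v <= ub,

with uptake bounds from Michaelis–Menten kinetics
`v_ub = v_max * S / (K_m + S)` at the current extracellular
concentrations.  The extracellular state then advances by the analytical
update (exact when `mu` and `v` are constant within the step):

    X_f = X_0 exp((mu - D) dt),          D = F/V
    S_f = S_0 + sum_i v_ij/(mu_i - D) X_0i (e^{(mu_i - D)dt} - 1)
              + D (S_feed - S_0) dt

with the analytic limit `v X_0 dt` when `|mu_i - D| < 1e-9`/h.  Dissolved
oxygen receives gas–liquid transfer `kLa (S* - S)` in place of feed
dilution.  Degenerate FBA optima are resolved by a parsimonious second
stage (minimum total absolute flux at the optimal growth rate) so
exchange fluxes are reproducible; an infeasible FBA zeroes that species'
rates for the step and is logged.

The anaerobe is gated on oxygen: when dissolved O2 exceeds 350 nM its FBA
is skipped and its growth rate and all its fluxes are zero for the step.
Gating applies to any species whose model has no O2 exchange (the
package's definition of an obligate anaerobe); it can be overridden per
call.

### Oxygen closure

Dissolved O2 is the fastest state variable by far: the supply
`kLa * S*` is of order 1 mmol/L/h while the near-gate pool is of order
1e-5 mM, so the pool turns over in well under a second — effectively
instantaneous relative to `dt = 0.01 h` (36 s).  A literal explicit
update at that `dt` cannot represent the sub-350 nM quasi-steady levels:
it either floors at the per-step refill `kLa S* dt` (~9 uM) or
oscillates between zero and that refill, toggling the anaerobe gate every
step.  The default closure (`oxygen_mode="quasi_steady"`) therefore
solves the algebraic balance

    kLa (S* - S) = sum_i X_i min(demand_i, v_max,i S / (K_m,i + S))

for S each step, where `demand_i` is the O2 flux the species' FBA
requested.  This is also what a dissolved-oxygen probe in the physical
reactor reads.  The one-transfer-term-per-step explicit update is
retained (`oxygen_mode="explicit"`, with an optional outflow-dilution
switch, default off) together with a stability diagnostic
(`ReactorConfig.explicit_o2_stability`); it is appropriate when
`dt (kLa + X v_max/K_m) << 1`.

### Substrate exhaustion

Fast carbon pools (residual glucose near its ~2 uM steady level) can
likewise be overdrawn within a discrete step.  Uptake bounds are
therefore additionally capped by per-step availability
`S_j / (X_i dt)` (`exhaustion_cap`, default on).  The printed update
equations are unchanged; concentrations are floored at zero and any
clamp is logged as an event.  With the cap the per-step map has a smooth
fixed point instead of a flip-flopping one, and halving `dt` moves 50-h
steady-state biomasses by well under 0.5%.

## Reactor parameters

| parameter | default | unit | note |
|---|---|---|---|
| V | 0.2 | L | culture volume |
| F_in = F_out | 0.04 | L/h | residence time 5 h, D = 0.2/h |
| kLa | 42 | 1/h | stirred-reactor scale; see calibration below |
| S* | 30.714e-3 at 1.7 ml/min | mM | Henry scaling of 6.056 mg/L air saturation at 37 C |
| dt | 0.01 | h | step-halving changes steady biomass < 0.5% |
| O2 gate | 350 | nM | anaerobe growth threshold |
| dextran feed | 0.0617 | mM | 1 g/L of a 100-glucose-unit glucan (anhydroglucose MW 162) |
| anaerobe inoculum | 0.0015 | g/L | 1 ml of OD 1 into 200 ml |
| extinction floor | 1e-9 | g/L | reporting floor; biomass is never hard-zeroed |
| classification floor | 1e-3 | g/L | state labels; just below the inoculum |

Oxygen input expressed as a sparge rate q (ml/min of a 50 ml/min gas
feed) maps linearly onto the saturation concentration:
`S*(q) = 189.25 uM * (q/50) / 0.2095`, giving the 30.714 uM calibration
point at q = 1.7.

## Toy community models

Both species are lumped-carbon stoichiometric models (glucose 6 C,
oligosaccharide 24 C = 4 glucose units, acetate 2 C, lactate 3 C,
biomass 40 mmol C/gCDW); every internal reaction is carbon-closed with
CO2 taking the balance, so the reactor-level carbon audit (inflow >=
outflow + biomass) holds by construction.

Aerobe routes (yields in gCDW/mmol): aerobic glucose (0.09, 2 O2/glc),
glucose fermentation (0.025, secreting 1.5 acetate + 2/3 lactate),
oligosaccharide versions of both (4x scaled), acetate oxidation (0.02,
0.8 O2) and lactate oxidation (0.03, 1.2 O2).  Oxygen uptake uses a
high-affinity terminal-oxidase entry (v_max 20 mmol/gCDW/h, K_m 100 nM,
the nM-scale affinity of cytochrome bd-type oxidases) — this is what
lets respiration pull dissolved O2 below the 350 nM gate.  All carbon
substrates use the literature defaults v_max 10 mmol/gCDW/h, K_m
0.01 mM.

The anaerobe has a single lumped hydrolysis-growth reaction per dextran
(100 glucose units): a configurable fraction (default 50%) of the
glucose is released to the shared pool; the rest supports growth at
0.04 gCDW per internal glucose, with the residual carbon secreted as
oligosaccharide/acetate/lactate/CO2 in fixed carbon fractions
(6/11, 3/11, 3/22, remainder).  Dextran kinetics v_max 0.2 mmol/gCDW/h
(20 glucose units/gCDW/h), K_m 0.01 mM give a maximum anaerobe growth
rate of 0.4/h, twice the dilution rate.  The anaerobe has no O2
exchange.

Calibration: with D = 0.2/h and 2 O2 per glucose, the aerobe-only state
consumes 0.4*G mmol O2/L/h against a supply of kLa*S* = 1.29; kLa = 42/h
was chosen once so that the oxygen budget saturates — and the anaerobe
gate opens — at a glucose feed just above 3 mM, inside the experimental
range of the modelled system.  The resulting forward tipping on a
0.25 mM grid is 3.25 mM; in the aerobe+anaerobe state the dextran-derived
carbon (~176 mmol O2-equivalents per dextran) keeps total demand above
supply even at 0 mM glucose, which is the hysteresis mechanism.

What the toys do **not** emulate: genome-scale route redundancy,
maintenance ATP, pH and gas-phase dynamics, aggregation (hypothesised in
the modelled system to extend hysteresis), or the published models'
literal fluxes — so passing tests demonstrate the mechanism and the
machinery, not quantitative agreement with any particular organism.
Curated SBML models can be substituted via `load_model`.

## Sweep protocol and classification

A sweep walks glucose feed (default 0.25–6 mM by 0.25) or oxygen input
(6 -> 0.5 ml/min by 0.5, then back) with state carryover, 50 h per
condition.  Conditions may finish early once 5-h window means of every
above-floor biomass change by < 5e-4 relative (checked from 15 h);
extending the settle time then changes nothing, which the suite verifies.
In forward passes the anaerobe is re-inoculated at 0.0015 g/L after any
washout (as in the modelled experiment); reverse passes never reseed, so
persistence there is informative.  States are labelled by the
classification floor; bistable conditions are exactly those where the
forward and reverse passes disagree, and the hysteresis ratio is the
reverse/forward aerobe biomass (~1 when monostable).

## Monod batch fitting

Batch growth is `dX/dt = X mu_max S/(S+K)` with consumption
`dS/dt = -X v_max S/(S+K)`.  The biomass factor in the consumption
equation is the package default (yield-linked depletion); a
biomass-independent variant (`consumption="as_printed"`) is provided
because the source formulation is ambiguous on this point, and the two
are not equivalent.  Both reduce to one autonomous substrate ODE with an
exact implicit solution t(S); trajectories are evaluated by inverting
t(S) on a dense grid refined in both the exponential phase (geometric in
X) and the depletion tail (geometric in S), giving ~1e-8 relative
accuracy at the default grid (4e4 points) and ~1e-6 at the MCMC grid
(1e3 points), against which a fine-step Runge–Kutta reference is the
independent test oracle.

The posterior shares (mu_max, K, v_max) across wells, with per-well
initial density and OD background and a fitted Gaussian noise scale.
Priors are weakly informative log-normals (kinetics, X0, sigma) and a
truncated normal on the background.  Sampling: emcee ensemble with
differential-evolution moves, 26 walkers x 1800 steps (600 burn-in),
initialised around a Nelder–Mead MAP estimate in log space; all
randomness is seeded.  Convergence is summarised by split-R-hat (flagged
above 1.1; typical values ~1.05 at the default length).  The synthetic
design mirrors a plate-reader experiment: four substrate concentrations
(0.125–0.5 % w/v), 10-minute sampling over 16 h, 0.005 AU noise.  At
these settings 20-replicate recovery shows per-parameter mean median
bias under 2%.  Pooled 90%-interval coverage sits below nominal (about
77% over 60 intervals): mu_max and v_max are strongly correlated through
the well-determined yield ratio mu_max/v_max, so when an unlucky noise
realisation shifts their joint scale by 3–5% both tight intervals miss
together, and misses double-count in the pooled tally.  Chain length is
not the cause (doubling it leaves coverage unchanged); the effect is a
property of the fixed-truth, correlated-parameter design.

## Reporter metabolites

The metabolic network is a bipartite undirected graph with one enzyme
node per gene-associated reaction and edges to its substrates and
products.  Currency metabolites (H+, water, ATP/ADP/AMP, phosphates,
NAD(P)(H), CoA, CO2, O2; configurable) and biomass pseudo-metabolites
are excluded, since they would otherwise dominate node degree.  Gene
p-values map to enzyme scores `Z = Phi^-1(1 - p)` (inverse normal CDF;
multi-gene enzymes take their smallest p; p is clamped at 1e-16 with a
warning).  Metabolites aggregate their k neighbouring enzymes either as
`(1/k) sum Z_i` (default, the plain mean) or `(1/sqrt(k)) sum Z_i` (the
Patil–Nielsen normalisation, which keeps unit variance under the null).
The two normalisations rank differently when degrees vary; both are
exposed because the method literature uses 1/sqrt(k) while the plain
mean is the more conservative default here.  An optional background
correction standardises each score against 1000 random same-size enzyme
sets (seeded); with it, permutation nulls on an adequately sized graph
centre within |0.1| of zero.  Note the toy aerobe graph (4 metabolites,
6 enzymes) is too small for stable background estimation — null
calibration uses the random bipartite generator instead.

## Problem sizes

Defaults used by the analysis scripts, the test-suite and
`scripts/acceptance.py`: 50-h conditions at dt = 0.01 h; glucose sweeps
of 24–25 conditions; an 11 x 12 glucose-oxygen stability map run in both
directions; 20 Monod replicates of 4 wells x 97 time points; 1000
permutation draws for the reporter null.  These sizes were chosen so the
whole analysis reruns from scratch on a single CPU in minutes while
keeping every estimate's Monte-Carlo error well inside the tolerances
the tests assert.

## Known limitations

- The quasi-steady oxygen closure assumes transfer/consumption
  equilibrate within one step; for very small kLa combined with very
  slow dynamics the explicit mode is the better choice.
- FBA within a step uses bounds evaluated at the step's start; at sharp
  transitions (gate openings, substrate exhaustion) rates lag by one
  step.
- With multiple species consuming the same scarce metabolite the
  availability cap is applied per species, so joint overdraw within one
  step is possible (it is clamped and logged).
- The Monod model has no lag, death or diauxie terms; misfit to real
  curves with those features will concentrate in the noise scale.
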