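"""Map the community's stability landscape over glucose and oxygen inputs.

Runs the forward/reverse glucose sweep at the baseline oxygen input, the
forward/reverse oxygen sweep at 3 mM glucose, and the full glucose x
oxygen stability map.  The sweeps locate the tipping points; the map
classifies each condition as monostable or bistable and records the
hysteresis ratio (reverse/forward aerobe steady biomass, ~1 where
monostable).

Outputs under results/: glucose_sweep_{forward,reverse}.tsv,
oxygen_sweep_{forward,reverse}.tsv, stability_map.tsv,
tipping_points.json.
"""

import json
from pathlib import Path

import numpy as np

from msh import (
    ReactorConfig,
    SweepProtocol,
    default_kinetics,
    hysteresis_ratio,
    make_toy_models,
    run_sweep,
    stability_map,
)
from msh.synth import DEXTRAN_FEED_MM

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    aerobe, anaerobe = make_toy_models()
    models = {"aerobe": aerobe, "anaerobe": anaerobe}
    kin = default_kinetics()
    cfg = ReactorConfig(s_feed={"glc_e": 0.0, "dex_e": DEXTRAN_FEED_MM})
    tips = {}

    # glucose sweep at the baseline 1.7 ml/min oxygen input
    grid = list(np.round(np.arange(0.25, 6.001, 0.25), 10))
    fwd = run_sweep(SweepProtocol("glucose_feed", grid, "forward"), cfg, models, kin)
    rev = run_sweep(
        SweepProtocol("glucose_feed", grid[::-1] + [0.0], "reverse"),
        cfg, models, kin, init=fwd.final_states[-1],
    )
    fwd.to_frame().to_csv(RESULTS / "glucose_sweep_forward.tsv", sep="\t", index=False)
    rev.to_frame().to_csv(RESULTS / "glucose_sweep_reverse.tsv", sep="\t", index=False)
    tips["glucose_forward"] = fwd.tipping_points
    tips["glucose_reverse"] = rev.tipping_points
    print("glucose forward tipping:", fwd.tipping_points)
    print("glucose reverse labels all aerobe_anaerobe:",
          all(l == "aerobe_anaerobe" for l in rev.labels))

    # oxygen sweep at 3 mM glucose
    cfg3 = cfg.with_feed("glc_e", 3.0)
    oxy = list(np.arange(0.5, 6.01, 0.5))
    ofwd = run_sweep(SweepProtocol("oxygen_inflow", list(reversed(oxy)), "forward"),
                     cfg3, models, kin)
    orev = run_sweep(SweepProtocol("oxygen_inflow", oxy, "reverse"),
                     cfg3, models, kin, init=ofwd.final_states[-1])
    ofwd.to_frame().to_csv(RESULTS / "oxygen_sweep_forward.tsv", sep="\t", index=False)
    orev.to_frame().to_csv(RESULTS / "oxygen_sweep_reverse.tsv", sep="\t", index=False)
    tips["oxygen_forward"] = ofwd.tipping_points
    tips["oxygen_reverse"] = orev.tipping_points
    print("oxygen forward tipping (anaerobe appears):", ofwd.tipping_points)
    print("oxygen reverse tipping (anaerobe lost):", orev.tipping_points)
    ratios = hysteresis_ratio(ofwd, orev)
    ratios.to_csv(RESULTS / "oxygen_hysteresis_ratio.tsv", sep="\t", index=False)

    # full stability map, 11 glucose conditions x 12 oxygen rates
    glucose = list(np.arange(1.0, 6.01, 0.5))
    df = stability_map(glucose, oxy, cfg, models, kin)
    df.to_csv(RESULTS / "stability_map.tsv", sep="\t", index=False)
    counts = df["stability"].value_counts().to_dict()
    print("stability map:", counts)

    with open(RESULTS / "tipping_points.json", "w") as fh:
        json.dump(tips, fh, indent=1)
    print(f"wrote sweep tables and {RESULTS}/stability_map.tsv")


if __name__ == "__main__":
    main()
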