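# JSON model dialect (`msh-model/1`)

A minimal, versioned JSON encoding of a species-level stoichiometric
model.  SBML (FBC) is supported for interoperability with curated
genome-scale models; the JSON dialect exists so the packaged toy models
are plain, diffable text with explicit carbon bookkeeping.

```json
{
  "format": "msh-model/1",
  "id": "toy_aerobe",
  "metabolites": [
    {"id": "glc_e", "compartment": "e", "carbon": 6}
  ],
  "reactions": [
    {
      "id": "GLC_AEROBIC",
      "stoichiometry": {"glc_e": -1, "o2_e": -2, "bm_aerobe": 0.09, "co2_e": 2.4},
      "lower_bound": 0,
      "upper_bound": 1000,
      "genes": ["ga_ptsG", "ga_glk"]
    }
  ],
  "objective": "BIOMASS_aerobe",
  "exchanges": {"glc_e": "EX_glc"}
}
```

Fields:

- `format` — must be `"msh-model/1"`.
- `metabolites[]` — `id` (compartment-suffixed), `compartment` tag, and
  `carbon` (atoms per molecule; used by carbon audits, `0` if unknown).
- `reactions[]` — `id`, a `stoichiometry` map (negative = consumed),
  flux bounds in mmol/gCDW/h, and an optional `genes` list for
  reporter-metabolite analysis.
- `objective` — the ID of the single biomass reaction.
- `exchanges` — metabolite ID -> exchange reaction ID for every
  externally tracked metabolite.  Exchange flux is positive for
  secretion into the environment and negative for uptake.

Validation on load enforces: one row/column per listed
metabolite/reaction, `lower_bound <= upper_bound` everywhere, exactly one
objective reaction, and exchange entries naming existing reactions.

SBML models are read and written through cobrapy; carbon counts travel in
metabolite formulae (`C6H12O6` or bare `C6`), gene associations in FBC
gene-product rules.  Bound values and stoichiometry round-trip exactly
between the two encodings.
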