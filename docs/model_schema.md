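# Model file formats

## JSON dialect (canonical, round-trip exact)

Top-level keys: `metabolites`, `reactions`, `params`, `biomass_reaction`.

```json
{
 "metabolites": [
  {"id": "g6p", "name": "", "compartment": "c",
   "conc_lower": 1e-05, "conc_upper": 100.0, "fixed_conc": null,
   "is_extracellular": false, "is_currency": false}
 ],
 "reactions": [
  {"id": "pgi", "stoichiometry": {"g6p": -1.0, "f6p": 1.0},
   "reversible": true, "flux_lower": -1000.0, "flux_upper": 1000.0,
   "dg0": {"value": 2.5, "stderr": 0.6, "category": "I"},
   "is_exchange": false}
 ],
 "params": {"T": 298.15, "R": 0.008314, "alpha": 4.0, "beta": 0.02,
            "w_plus": 1000.0, "delta": 1.0, "c_lower": 1e-05, "c_upper": 100.0},
 "biomass_reaction": null
}
```

* Concentrations are mM; energies kJ/mol; fluxes mmol/(gDW·h).
* `dg0` is `null` for reactions without a standard Gibbs energy; such
  reactions are outside R_G and carry no thermodynamic constraint.
* `stoichiometry` maps metabolite ids to signed coefficients; zero
  coefficients are dropped on load.
* Exchange reactions have stoichiometry on a single boundary metabolite.
* Every field except `id` and `stoichiometry` has the default shown above.

## TSV dialect

A stoichiometry table with columns `reaction_id`, `metabolite_id`,
`coefficient`, plus an optional companion table `<stem>.reactions.tsv`
with columns `reaction_id`, `reversible`, `flux_lower`, `flux_upper`,
`is_exchange`, `dg0`, `dg0_stderr`.  Metabolites not described elsewhere
get default attributes.

## SBML

Read-only (Level 3 + FBC, via cobrapy): bounds come from FBC parameters,
reversibility from a negative lower bound, exchange status from boundary
reactions, extracellular flags from compartments starting with "e".
Standard Gibbs energies are not read from SBML; attach them afterwards or
estimate them with the component-contribution module.

## Medium (JSON or YAML)

Keys: `exchange_bounds` (reaction id → [lower, upper]),
`extracellular_concs` and `currency_concs` (metabolite id → mM),
`measured_fluxes` (reaction id → [value, tolerance], applied to net flux
across split pairs), `growth_rate` ([value, tolerance] on the biomass
reaction, 1/h).
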