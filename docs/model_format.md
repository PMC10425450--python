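# JSON model dialect

A `plm` model is one JSON document with fixed field names. The dialect
round-trips every field of the in-memory data model exactly (unlike SBML,
whose double formatting is limited to 15 significant digits).

```json
{
  "format": "plm-model",
  "version": 1,
  "id": "toy",
  "compartments": {"c": "cytosol", "h": "chloroplast"},
  "metabolites": [
    {
      "id": "hexose_c",
      "name": "hexose",
      "compartment": "c",
      "formula": "C6H12O6",
      "charge": 0,
      "annotations": {"kegg": "C00031", "chebi": "CHEBI:4167"}
    }
  ],
  "reactions": [
    {
      "id": "SUC_SYN",
      "name": "sucrose synthesis",
      "stoichiometry": {"hexose_c": -2.0, "sucrose_c": 1.0},
      "lower_bound": 0.0,
      "upper_bound": 1000000.0,
      "gpr": "SPS1 or SPS2",
      "subsystem": "Sugar metabolism",
      "flags": []
    }
  ],
  "genes": ["SPS1", "SPS2"],
  "objective": {"reactions": {"biomass": 1.0}, "direction": "max"}
}
```

Field notes:

- `formula` is a Hill-style element-count string with integer counts;
  charge is carried in the separate integer `charge` field and `R` groups
  are rejected.
- `annotations` maps namespace to identifier; `kegg` and `chebi` are the
  namespaces used for metabolite matching during module integration.
- `stoichiometry` maps metabolite ids to signed coefficients (substrates
  negative). Exchange reactions are written one-sided (a single
  metabolite, no explicit boundary species); uptake is negative flux.
- `gpr` is a rule string over gene ids with case-insensitive `and`/`or`
  and parentheses; `""` means no rule.
- `flags` is a subset of `exchange`, `demand`, `maintenance`, `transport`,
  `slime`, `biomass`, `linker`. Flags drive stage behavior (balance-check
  exemptions, lethality analysis scope, diel linker handling).
- `genes` lists the model's gene universe; genes not appearing in any GPR
  are preserved through this field.
- `objective.reactions` maps reaction ids to linear objective
  coefficients (usually one entry; diel models may weight two phase
  biomass reactions).

In SBML (Level 3 + `fbc`), `flags` and `subsystem` are carried in reaction
notes as `plm_flags` (semicolon-separated) and `plm_subsystem`; metabolite
annotations map to identifiers.org CV terms (`kegg` ↔ `kegg.compound`,
`chebi` ↔ `chebi`).
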