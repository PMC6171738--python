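{
  "description": "Defaults for the reconstructed per-cell fixture: a pooled boolean cells x transmitters matrix whose recomputed directed coexpression ratios reproduce every packaged observed percentage exactly at one-decimal rounding. The fixture is a consistent witness to the published summary statistics, not a claim about the actual per-cell data.",
  "replicates": 12,
  "population_per_replicate": 360,
  "count_window_sd": 1.0,
  "unconstrained_pairs": [
    ["FMRF", "MIP"],
    ["AST-A", "TK"],
    ["AST-A", "FMRF"],
    ["AST-A", "Mas-AT"],
    ["AST-A", "MIP"]
  ],
  "unconstrained_pairs_note": "FMRF/MIP coexpression was not usable in the source data (under-labeled MIP runs) and AST-A peptide-peptide ratios were never reported; both directions of each listed pair are left unconstrained in the fixture and excluded from default rule pools and weighted-SDI pair sets.",
  "gaba_policy": "minimal",
  "gaba_policy_note": "The reported per-peptide GABA-coexpression percentages and the MIP/Mas-AT overlap jointly require at least |GABA & MIP| + |GABA & Mas-AT| - |MIP & Mas-AT| GABA-positive cells, which exceeds the reported ~170 GABAergic LNs per antennal lobe; the fixture uses the minimal consistent GABA total and records it here at build time.",
  "placement_order": [
    "hub peptide interval first (MIP), with the fully nested peptide (TK) at its start",
    "second peptide (Mas-AT) overlapping the hub tail by the constrained overlap, avoiding TK",
    "GABA segments sized to each peptide's constrained GABA overlap with maximal reuse of shared cells",
    "third peptide (FMRF) split across the Mas-AT overlap, a GABA-positive hub segment, and a free non-GABA tail",
    "unconstrained peptides (AST-A) on GABA-positive Mas-AT cells plus a free non-GABA tail"
  ]
}
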