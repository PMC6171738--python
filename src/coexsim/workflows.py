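"""Canonical end-to-end comparisons built from the packaged observed data.

The observed summary statistics carry no replicate SDs (they were never
published), so scoring models with SDIs needs SDs from somewhere.  The
workflow here regenerates the observed coexpression structure as a
synthetic replicate dataset — planting every printed ratio as a rule at the
panel's count noise — and uses the across-replicate ratio SDs as the
observed SDs, while the observed means and overlap weights come from the
reconstructed per-cell fixture.  This keeps every number flowing through
the package's own data path.
"""

from __future__ import annotations

import numpy as np

from .metrics import ObservedCoexpression
from .observed import (
    observed_panel,
    observed_ratio_frame,
    reconstruct_fixture,
)
from .rules import ModelSpec, Rule
from .synthetic import SyntheticDesign, generate_replicates

__all__ = [
    "observed_regeneration_rules",
    "default_sdi_pairs",
    "observed_with_synthetic_sds",
    "canonical_models",
]


def observed_regeneration_rules(include_gaba: bool = True) -> list[Rule]:
    """Every printed ratio as a rule, ordered so each target builds in turn.

    The packaged constraints chain (TK feeds MIP, MIP feeds Mas-AT, Mas-AT
    feeds FMRF, everything feeds GABA), so rules are ordered by build stage
    rather than by table row.
    """
    frame = observed_ratio_frame()
    pct = {(r["source"], r["target"]): float(r["percent"]) / 100.0
           for _, r in frame.iterrows()}
    stage_order = [
        ("TK", "MIP"),
        ("MIP", "Mas-AT"), ("TK", "Mas-AT"),
        ("Mas-AT", "FMRF"), ("TK", "FMRF"),
        ("TK", "GABA"), ("FMRF", "GABA"), ("Mas-AT", "GABA"),
        ("MIP", "GABA"), ("AST-A", "GABA"),
    ]
    rules = []
    for source, target in stage_order:
        if (source, target) not in pct:
            continue
        if not include_gaba and target == "GABA":
            continue
        rules.append(Rule(source, target, pct[(source, target)]))
    return rules


def default_sdi_pairs(include_gaba: bool = True) -> list[tuple[str, str]]:
    """The directed pairs entering the weighted SDI by default.

    Printed pairs plus the overlap-identity reverses of the peptide-peptide
    ones.  GABA appears only as a target (its own cell total was estimated,
    not counted per run, so GABA-sourced ratios are not treated as data).
    """
    frame = observed_ratio_frame()
    pairs: list[tuple[str, str]] = []
    for _, row in frame.iterrows():
        source, target = str(row["source"]), str(row["target"])
        if target == "GABA" and not include_gaba:
            continue
        pairs.append((source, target))
        if target != "GABA":
            pairs.append((target, source))
    return pairs


def observed_with_synthetic_sds(
    panel=None,
    replicates: int = 12,
    seed: int = 0,
    include_gaba: bool = True,
    fixture_replicates: int = 12,
) -> tuple[ObservedCoexpression, list[tuple[str, str]]]:
    """Observed summary for SDI scoring: fixture means, regenerated SDs.

    Returns the summary and the default directed pair list.  Means and
    overlap weights are recomputed from the reconstructed fixture (scaled
    back to one replicate); SDs are across-replicate ratio SDs of a
    synthetic regeneration that plants every printed ratio at the panel's
    count noise.
    """
    panel = observed_panel() if panel is None else panel
    fixture = reconstruct_fixture(panel=panel, replicates=fixture_replicates)
    design = SyntheticDesign(
        panel=panel,
        planted_rules=tuple(observed_regeneration_rules(include_gaba=True)),
        n_replicates=replicates,
        seed=seed,
    )
    _, regenerated = generate_replicates(design)

    pairs = default_sdi_pairs(include_gaba=include_gaba)
    k = panel.n_transmitters
    mean = np.full((k, k), np.nan)
    sd = np.full((k, k), np.nan)
    overlap = np.full((k, k), np.nan)
    for source, target in pairs:
        i, j = panel.index(source), panel.index(target)
        mean[i, j] = fixture.table.ratio_of(source, target)
        overlap[i, j] = fixture.table.overlap_of(source, target) / fixture.manifest["replicates"]
        io = regenerated.transmitters.index(source)
        jo = regenerated.transmitters.index(target)
        sd[i, j] = regenerated.ratio_sd[io, jo]
    observed = ObservedCoexpression(
        transmitters=panel.transmitters,
        ratio_mean=mean,
        ratio_sd=sd,
        overlap=overlap,
        count_mean=np.asarray(panel.count_mean),
        count_sd=np.asarray(panel.count_sd),
    )
    return observed, pairs


def canonical_models(
    panel=None,
    n_iterations: int = 10_000,
    seed: int = 0,
    gaba_population: float = 170.0,
    rule_probability: float = 0.42,
) -> list[ModelSpec]:
    """The three headline models: independent, GABA-constrained, single rule.

    The GABA constraint restricts the population to the GABAergic LN total
    (~170 cells); the single-rule model additionally clamps the fraction of
    MIP-positive cells coexpressing Mas-AT to its observed value.
    """
    panel = observed_panel() if panel is None else panel
    return [
        ModelSpec(panel=panel, n_iterations=n_iterations, seed=seed,
                  label="independent"),
        ModelSpec(panel=panel, population_mean=gaba_population,
                  n_iterations=n_iterations, seed=seed, label="gaba-constrained"),
        ModelSpec(panel=panel, population_mean=gaba_population,
                  rules=(Rule("MIP", "Mas-AT", rule_probability),),
                  n_iterations=n_iterations, seed=seed, label="mip-masat-rule"),
    ]
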