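"""Packaged observed data and reconstruction of a consistent per-cell fixture.

The package ships the published summary statistics for *Manduca sexta*
antennal-lobe local interneurons: per-transmitter mean +/- SD cell counts
(five neuropeptide families plus GABA in a population of ~360 LNs) and the
directed coexpression percentages reported alongside them.  Because no
per-cell data are deposited, this module also reconstructs an integer
per-cell boolean matrix — the *fixture* — whose recomputed directed ratios
reproduce every printed percentage exactly at one-decimal rounding.  The
fixture is a deterministic, consistent witness to the printed summary
statistics, not a reconstruction of the actual cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .metrics import ObservedCoexpression
from .population import (
    CellPopulationMatrix,
    CoexpressionRatioTable,
    TransmitterPanel,
    coexpression_ratios,
    round_half_up,
)

__all__ = [
    "FixtureError",
    "FixtureResult",
    "observed_panel",
    "observed_ratio_frame",
    "observed_coexpression",
    "default_excluded_pairs",
    "default_rule_pool",
    "derive_reverse_ratio",
    "reconstruct_fixture",
    "load_panel_csv",
    "write_panel_csv",
    "load_ratio_csv",
    "write_ratio_csv",
]

PANEL_COLUMNS = ("transmitter", "count_mean", "count_sd")
RATIO_COLUMNS = ("source", "target", "percent")

# FMRF/MIP ratios could not be measured reliably in the source data and
# AST-A peptide-peptide ratios were never reported: both directions of each
# pair are excluded from default rule pools and weighted-SDI pair sets.
_EXCLUDED_UNDIRECTED = (
    ("FMRF", "MIP"),
    ("AST-A", "TK"),
    ("AST-A", "FMRF"),
    ("AST-A", "Mas-AT"),
    ("AST-A", "MIP"),
)


class FixtureError(ValueError):
    """The printed percentages cannot be realized under the given windows."""


def _data_path(name: str):
    return resources.files("coexsim.data").joinpath(name)


def _round1(x: float) -> float:
    """Round a percentage to one decimal, half away from zero."""
    return math.floor(x * 10.0 + 0.5) / 10.0


def load_panel_csv(
    path,
    population_mean: float = 360.0,
    population_sd: float = 0.0,
) -> tuple[TransmitterPanel, pd.DataFrame]:
    """Read a transmitter panel CSV (``transmitter,count_mean,count_sd``).

    Returns the panel and a DataFrame of any extra columns (preserved for a
    lossless round trip through :func:`write_panel_csv`).
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing required columns: {missing}")
    for idx, row in df.iterrows():
        if row["count_mean"] < 0 or row["count_sd"] < 0:
            raise ValueError(
                f"panel CSV row {idx} ({row['transmitter']!r}): negative count_mean/count_sd"
            )
    panel = TransmitterPanel(
        transmitters=tuple(df["transmitter"].astype(str)),
        count_mean=tuple(df["count_mean"].astype(float)),
        count_sd=tuple(df["count_sd"].astype(float)),
        population_mean=population_mean,
        population_sd=population_sd,
    )
    extras = df[[c for c in df.columns if c not in PANEL_COLUMNS]]
    return panel, extras


def write_panel_csv(panel: TransmitterPanel, path, extras: pd.DataFrame | None = None) -> None:
    df = panel.to_frame()
    if extras is not None:
        for col in extras.columns:
            df[col] = extras[col].to_numpy()
    df.to_csv(path, index=False)


def load_ratio_csv(path) -> pd.DataFrame:
    """Read a directed-ratio CSV (``source,target,percent`` in 0..100)."""
    df = pd.read_csv(path)
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratio CSV missing required columns: {missing}")
    for idx, row in df.iterrows():
        pct = float(row["percent"])
        if not (0.0 <= pct <= 100.0):
            raise ValueError(
                f"ratio CSV row {idx} ({row['source']}->{row['target']}): "
                f"percent {pct} outside [0, 100]"
            )
    return df


def write_ratio_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def observed_panel(
    gaba_sd: float = 0.0,
    population_mean: float = 360.0,
    population_sd: float = 0.0,
) -> TransmitterPanel:
    """The packaged observed panel (five neuropeptides plus GABA).

    The GABA SD was not reported; it defaults to 0 and can be overridden.
    """
    panel, _ = load_panel_csv(
        _data_path("observed_panel.csv"),
        population_mean=population_mean,
        population_sd=population_sd,
    )
    if gaba_sd:
        sds = list(panel.count_sd)
        sds[panel.index("GABA")] = float(gaba_sd)
        panel = TransmitterPanel(
            panel.transmitters, panel.count_mean, tuple(sds),
            population_mean, population_sd,
        )
    return panel


def observed_ratio_frame() -> pd.DataFrame:
    """The packaged observed directed percentages."""
    return load_ratio_csv(_data_path("observed_ratios.csv"))


def default_excluded_pairs() -> tuple[tuple[str, str], ...]:
    """Directed pairs excluded from default rule pools and SDI pair sets."""
    out = []
    for a, b in _EXCLUDED_UNDIRECTED:
        out.append((a, b))
        out.append((b, a))
    return tuple(out)


def derive_reverse_ratio(ratio_xy: float, count_x: float, count_y: float) -> float:
    """Reverse a directed ratio through the overlap identity.

    ratio(X->Y) * n_X = ratio(Y->X) * n_Y = |X AND Y|, so the reverse ratio
    is ``ratio_xy * count_x / count_y`` (clipped to [0, 1]).
    """
    if count_y <= 0:
        raise ValueError("count_y must be > 0 to derive a reverse ratio")
    return float(np.clip(ratio_xy * count_x / count_y, 0.0, 1.0))


def observed_coexpression(
    panel: TransmitterPanel | None = None,
    ratios: pd.DataFrame | None = None,
    derive_reverse: bool = True,
) -> ObservedCoexpression:
    """Observed directed ratios as a matrix summary.

    Reverse directions of each printed ratio are filled via the overlap
    identity when ``derive_reverse`` is set.  Replicate SDs were not printed,
    so ``ratio_sd`` is NaN throughout; SDI computations need SDs supplied
    from synthetic replicates (:mod:`coexsim.synthetic`) or user data.
    """
    panel = observed_panel() if panel is None else panel
    ratios = observed_ratio_frame() if ratios is None else ratios
    k = panel.n_transmitters
    mean = np.full((k, k), np.nan)
    overlap = np.full((k, k), np.nan)
    np.fill_diagonal(mean, 1.0)
    counts = np.asarray(panel.count_mean)
    np.fill_diagonal(overlap, counts)
    for _, row in ratios.iterrows():
        i = panel.index(str(row["source"]))
        j = panel.index(str(row["target"]))
        frac = float(row["percent"]) / 100.0
        mean[i, j] = frac
        overlap[i, j] = overlap[j, i] = frac * counts[i]
        if derive_reverse and np.isnan(mean[j, i]) and counts[j] > 0:
            mean[j, i] = derive_reverse_ratio(frac, counts[i], counts[j])
    return ObservedCoexpression(
        transmitters=panel.transmitters,
        ratio_mean=mean,
        ratio_sd=np.full((k, k), np.nan),
        overlap=overlap,
        count_mean=counts,
        count_sd=np.asarray(panel.count_sd),
    )


def default_rule_pool(
    panel: TransmitterPanel | None = None,
    ratios: pd.DataFrame | None = None,
    include_gaba: bool = False,
):
    """Candidate rules clamping each observed ratio to its printed value.

    Mirrors the constrained-model procedure: the pool is the observed-ratio
    table itself.  GABA-targeted rules are off by default because the GABA
    constraint is normally expressed as a population-size restriction
    instead.
    """
    from .rules import Rule

    panel = observed_panel() if panel is None else panel
    ratios = observed_ratio_frame() if ratios is None else ratios
    excluded = set(default_excluded_pairs())
    pool = []
    for _, row in ratios.iterrows():
        src, tgt = str(row["source"]), str(row["target"])
        if (src, tgt) in excluded:
            continue
        if not include_gaba and tgt == "GABA":
            continue
        pool.append(Rule(src, tgt, float(row["percent"]) / 100.0))
    return pool


@dataclass
class FixtureResult:
    """A reconstructed per-cell fixture plus its audit trail."""

    matrix: CellPopulationMatrix
    table: CoexpressionRatioTable
    counts: dict[str, int]
    manifest: dict

    def percent(self, source: str, target: str, decimals: int = 1) -> float:
        value = 100.0 * self.table.ratio_of(source, target)
        return math.floor(value * 10 ** decimals + 0.5) / 10 ** decimals


def _search_counts(
    panel: TransmitterPanel,
    constraints: dict[str, dict[str, float]],
    replicates: int,
    sd_window: float,
) -> tuple[dict[str, int], dict[str, dict[str, int]]]:
    """Brute-force integer (k, n) search for each constrained transmitter.

    For transmitter X with window ``replicates * (mean +/- sd_window * sd)``,
    choose the pooled count n (and per-target overlaps k) so that every
    printed percentage from X is matched exactly at one-decimal rounding,
    minimizing the total absolute deviation; ties break toward smaller n.
    """
    counts: dict[str, int] = {}
    overlaps: dict[str, dict[str, int]] = {}
    for name, targets in constraints.items():
        mean = panel.count_mean[panel.index(name)]
        sd = panel.count_sd[panel.index(name)]
        lo = max(1, math.ceil(replicates * (mean - sd_window * sd)))
        hi = max(lo, math.floor(replicates * (mean + sd_window * sd)))
        best = None
        for n in range(lo, hi + 1):
            ks = {}
            score = 0.0
            feasible = True
            for target, pct in targets.items():
                kk = round_half_up(pct * n / 100.0)
                if _round1(100.0 * kk / n) != _round1(pct):
                    feasible = False
                    break
                ks[target] = kk
                score += abs(100.0 * kk / n - pct)
            if feasible and (best is None or score < best[0]):
                best = (score, n, ks)
        if best is None:
            raise FixtureError(
                f"no pooled count for {name!r} in [{lo}, {hi}] matches its printed "
                f"percentages {targets} at one-decimal rounding"
            )
        counts[name] = best[1]
        overlaps[name] = best[2]
    return counts, overlaps


def reconstruct_fixture(
    panel: TransmitterPanel | None = None,
    ratios: pd.DataFrame | None = None,
    replicates: int = 12,
    companion: str = "GABA",
    sd_window: float = 1.0,
    widen_factor: float = 2.0,
) -> FixtureResult:
    """Build a pooled per-cell boolean matrix realizing every printed ratio.

    The pooled scale (default 12 replicates, i.e. both antennal lobes of six
    brains) is needed because percentages such as 84.6% are not realizable
    with ~12 cells.  Construction is deterministic (no RNG): integer counts
    and overlaps come from :func:`_search_counts` (window widened once by
    ``widen_factor`` if needed), then memberships are placed greedily on the
    cell axis.

    The placement handles the constraint topology of the packaged data: one
    peptide fully nested in a "hub" peptide and excluded from the others
    (TK in MIP), a hub-to-second overlap (MIP/Mas-AT), a second-to-third
    overlap (Mas-AT/FMRF), unconstrained extra peptides (AST-A), and a
    companion (GABA) overlapping every peptide.  The companion total is the
    minimal value consistent with the printed percentages (see manifest).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    panel = observed_panel() if panel is None else panel
    ratios = observed_ratio_frame() if ratios is None else ratios
    if companion not in panel.transmitters:
        raise ValueError(f"companion {companion!r} not in panel")

    peptides = [t for t in panel.transmitters if t != companion]
    constraints: dict[str, dict[str, float]] = {p: {} for p in peptides}
    for _, row in ratios.iterrows():
        src, tgt = str(row["source"]), str(row["target"])
        if src == companion:
            raise FixtureError("companion-sourced ratios are not supported")
        constraints[src][tgt] = float(row["percent"])

    try:
        counts, overlaps = _search_counts(panel, constraints, replicates, sd_window)
    except FixtureError:
        counts, overlaps = _search_counts(
            panel, constraints, replicates, sd_window * widen_factor
        )

    # --- classify the constraint topology -------------------------------
    nested = [
        p for p in peptides
        if any(t != companion and pct == 100.0 for t, pct in constraints[p].items())
    ]
    if len(nested) != 1:
        raise FixtureError("expected exactly one fully nested peptide (a 100% rule)")
    t_nest = nested[0]
    hub = next(t for t, pct in constraints[t_nest].items() if t != companion and pct == 100.0)
    hub_targets = [t for t, pct in constraints[hub].items() if t != companion]
    if len(hub_targets) != 1:
        raise FixtureError("expected exactly one hub-to-second constraint")
    second = hub_targets[0]
    second_targets = [t for t, pct in constraints[second].items() if t != companion]
    if len(second_targets) != 1:
        raise FixtureError("expected exactly one second-to-third constraint")
    third = second_targets[0]
    for t, pct in constraints[t_nest].items():
        if t not in (companion, hub) and pct != 0.0:
            raise FixtureError(f"nested peptide has unsupported constraint to {t!r}")
    free = [p for p in peptides if p not in (t_nest, hub, second, third)]

    n_cells = replicates * round_half_up(panel.population_mean)
    nT, nM, nA, nF = counts[t_nest], counts[hub], counts[second], counts[third]
    oMA = overlaps[hub][second]
    oAF = overlaps[second][third]
    g = {p: overlaps[p][companion] for p in peptides if companion in overlaps[p]}
    if set(g) != set(peptides):
        raise FixtureError("every peptide needs a companion (GABA) constraint")

    a = g[hub] - oMA - g[t_nest]          # companion cells in hub-only territory
    b = g[second] - oMA                   # companion cells in second-only territory
    checks = [
        (nT + oMA <= nM, "nested peptide and hub/second overlap exceed hub count"),
        (oAF <= oMA, "second/third overlap exceeds hub/second overlap region"),
        (oAF <= g[third], "third peptide's companion overlap below its second overlap"),
        (a >= 0, "hub companion overlap too small for nested+shared cells"),
        (a <= nM - oMA - nT, "hub-only region too small for its companion cells"),
        (0 <= b <= nA - oMA, "second-only region cannot hold its companion cells"),
        (g[third] - oAF <= a, "hub companion region too small for third peptide"),
        (g[t_nest] <= nT, "nested companion overlap exceeds nested count"),
        (oMA <= nA, "hub/second overlap exceeds second count"),
        (oAF <= nF, "second/third overlap exceeds third count"),
    ]
    for ok, message in checks:
        if not ok:
            raise FixtureError(f"placement infeasible: {message}")

    # --- place memberships on the cell axis -----------------------------
    membership = np.zeros((n_cells, panel.n_transmitters), dtype=bool)

    def put(name: str, *segments: tuple[int, int]) -> None:
        j = panel.index(name)
        for start, stop in segments:
            if start < 0 or stop > n_cells:
                raise FixtureError(f"segment for {name!r} outside the population")
            membership[start:stop, j] = True

    put(hub, (0, nM))
    put(t_nest, (0, nT))
    put(second, (nM - oMA, nM - oMA + nA))
    # Companion: nested head, hub-only block, all shared hub/second cells,
    # and a second-only block -- the minimal consistent companion set.
    put(companion, (0, g[t_nest]), (nT, nT + a), (nM - oMA, nM), (nM, nM + b))
    # Third peptide: its second-overlap inside the (all-companion) shared
    # region, its remaining companion cells on hub-only companion cells, and
    # a companion-negative tail in free territory.
    tail = nM - oMA + nA
    put(
        third,
        (nM - oMA, nM - oMA + oAF),
        (nT, nT + (g[third] - oAF)),
        (tail, tail + (nF - g[third])),
    )
    tail += nF - g[third]
    for name in free:
        if g[name] > b:
            raise FixtureError(
                f"placement infeasible: companion overlap of {name!r} exceeds the "
                "second-only companion region"
            )
        n_free = counts[name]
        put(name, (nM, nM + g[name]), (tail, tail + (n_free - g[name])))
        tail += n_free - g[name]
    if tail > n_cells:
        raise FixtureError("placement infeasible: population too small for the tails")

    matrix = CellPopulationMatrix(membership, panel.transmitters)
    table = coexpression_ratios(matrix)

    # --- verify every printed percentage at one-decimal rounding --------
    realized = {}
    for _, row in ratios.iterrows():
        src, tgt = str(row["source"]), str(row["target"])
        got = _round1(100.0 * table.ratio_of(src, tgt))
        want = _round1(float(row["percent"]))
        realized[f"{src}->{tgt}"] = got
        if got != want:
            raise FixtureError(
                f"fixture verification failed for {src}->{tgt}: realized {got}, printed {want}"
            )

    gaba_total = int(matrix.column(companion).sum())
    all_counts = {name: int(c) for name, c in zip(panel.transmitters, matrix.counts)}
    manifest = {
        "replicates": replicates,
        "n_cells": n_cells,
        "counts": all_counts,
        "per_replicate_counts": {k: v / replicates for k, v in all_counts.items()},
        "realized_percent": realized,
        "companion": companion,
        "companion_total": gaba_total,
        "companion_per_replicate": gaba_total / replicates,
        "companion_note": (
            "minimal companion total consistent with the printed percentages: "
            "|G&hub| + |G&second| - |hub&second|"
        ),
        "unconstrained_pairs": [list(p) for p in _EXCLUDED_UNDIRECTED],
        "roles": {
            "nested": t_nest, "hub": hub, "second": second,
            "third": third, "free": free,
        },
    }
    return FixtureResult(matrix=matrix, table=table, counts=all_counts, manifest=manifest)
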