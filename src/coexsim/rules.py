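"""Rule-constrained coexpression models.

A *rule* clamps one directed coexpression probability to a fixed value: for
rule (X -> Y, p), exactly ``round(p * n_X)`` of the X-positive cells are also
made Y-positive, and the remainder of Y's quota is distributed uniformly among
cells that are not X-positive.  Everything else still emerges from independent
assignment, so a rule asks "if this one relationship is taken as given, how
much of the remaining coexpression structure follows?".

Rule semantics are monotone (set-only): a later rule never removes a
membership created by an earlier one.  When several rules share a target, the
forced sets are built rule by rule and the residual quota is filled once per
target; interacting rules that push a realized ratio away from its clamp are
reported in the realization log rather than silently corrected.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .population import (
    TransmitterPanel,
    CellPopulationMatrix,
    assign_cells,
    draw_count,
    draw_population_size,
    round_half_up,
)

__all__ = ["Rule", "ModelSpec", "apply_rules", "realize_population", "enumerate_rule_models"]


@dataclass(frozen=True)
class Rule:
    """A forced directed coexpression probability: P(Y | X) = probability."""

    source: str
    target: str
    probability: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("rule source and target must differ")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("rule probability must be in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}@{self.probability:g}"

    def to_dict(self) -> dict:
        return {"source": self.source, "target": self.target, "probability": self.probability}

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(str(d["source"]), str(d["target"]), float(d["probability"]))


@dataclass(frozen=True)
class ModelSpec:
    """A complete model: panel + population size + rules + run parameters."""

    panel: TransmitterPanel
    rules: tuple[Rule, ...] = ()
    population_mean: float | None = None  # None -> use panel.population_mean
    population_sd: float | None = None
    n_iterations: int = 10_000
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        seen = set()
        for rule in self.rules:
            if rule.source not in self.panel.transmitters:
                raise ValueError(f"rule source {rule.source!r} not in panel")
            if rule.target not in self.panel.transmitters:
                raise ValueError(f"rule target {rule.target!r} not in panel")
            key = (rule.source, rule.target)
            if key in seen:
                raise ValueError(f"duplicate rule for pair {key}")
            seen.add(key)
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        if not self.rules:
            return "independent"
        return "+".join(r.label for r in self.rules)

    def effective_panel(self) -> TransmitterPanel:
        """Panel with the spec's population-size override applied."""
        if self.population_mean is None and self.population_sd is None:
            return self.panel
        mean = self.panel.population_mean if self.population_mean is None else self.population_mean
        sd = self.panel.population_sd if self.population_sd is None else self.population_sd
        return self.panel.with_population(mean, sd)

    def n_rules(self) -> int:
        return len(self.rules)

    def to_dict(self) -> dict:
        panel = self.effective_panel()
        return {
            "label": self.label,
            "transmitters": list(panel.transmitters),
            "count_mean": list(panel.count_mean),
            "count_sd": list(panel.count_sd),
            "population_mean": panel.population_mean,
            "population_sd": panel.population_sd,
            "rules": [r.to_dict() for r in self.rules],
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def apply_rules(
    membership: np.ndarray,
    transmitters: Sequence[str],
    drawn_counts: dict[str, int],
    rules: Sequence[Rule],
    rng: np.random.Generator,
) -> list[str]:
    """Apply coexpression rules in place, then fill residual target quotas.

    ``membership`` must already hold the independent assignments for every
    transmitter that is *not* a rule target (sources before their rules fire).
    Rules are processed grouped by target in order of first appearance; within
    a group zero-probability rules act as exclusion zones for the other rules'
    forced picks and for the residual fill.  Returns a list of warning strings
    for capped/inflated quotas or interacting-rule conflicts.
    """
    transmitters = list(transmitters)
    n_cells = membership.shape[0]
    col = {name: transmitters.index(name) for name in transmitters}
    logs: list[str] = []

    targets: list[str] = []
    for rule in rules:
        if rule.target not in targets:
            targets.append(rule.target)

    for target in targets:
        group = [r for r in rules if r.target == target]
        jt = col[target]
        zero_mask = np.zeros(n_cells, dtype=bool)
        for rule in group:
            if rule.probability == 0.0:
                zero_mask |= membership[:, col[rule.source]]

        for rule in group:
            js = col[rule.source]
            source_cells = membership[:, js]
            n_x = int(source_cells.sum())
            if rule.probability == 0.0:
                bad = int((source_cells & membership[:, jt]).sum())
                if bad:
                    logs.append(
                        f"rule {rule.label}: {bad} {rule.source}-positive cells already "
                        f"{target}-positive (interacting rules)"
                    )
                continue
            want = round_half_up(rule.probability * n_x) if n_x else 0
            have = int((source_cells & membership[:, jt]).sum())
            if have > want:
                logs.append(
                    f"rule {rule.label}: realized overlap {have} exceeds clamp {want} "
                    f"(interacting rules)"
                )
                continue
            eligible = np.flatnonzero(source_cells & ~membership[:, jt] & ~zero_mask)
            need = want - have
            if need > eligible.size:
                logs.append(
                    f"rule {rule.label}: only {eligible.size} eligible source cells for "
                    f"{need} forced memberships (capped)"
                )
                need = eligible.size
            if need:
                chosen = rng.permutation(eligible.size)[:need]
                membership[eligible[chosen], jt] = True

        # Residual quota: bring the target column up to its drawn count using
        # cells outside every rule source (so the clamped ratios stay exact).
        quota = drawn_counts[target]
        current = int(membership[:, jt].sum())
        if current > quota:
            logs.append(
                f"target {target}: forced memberships ({current}) exceed drawn count "
                f"({quota}); count inflated for this iteration"
            )
            drawn_counts[target] = current
            continue
        source_any = np.zeros(n_cells, dtype=bool)
        for rule in group:
            source_any |= membership[:, col[rule.source]]
        pool = np.flatnonzero(~source_any & ~membership[:, jt])
        residual = quota - current
        if residual > pool.size:
            logs.append(
                f"target {target}: residual quota {residual} exceeds {pool.size} "
                f"available non-source cells (capped)"
            )
            residual = pool.size
            drawn_counts[target] = current + residual
        if residual:
            chosen = rng.permutation(pool.size)[:residual]
            membership[pool[chosen], jt] = True

    return logs


def realize_population(
    panel: TransmitterPanel,
    rules: Sequence[Rule],
    rng: np.random.Generator,
) -> tuple[CellPopulationMatrix, dict[str, int], list[str]]:
    """One realization of the (possibly rule-constrained) model.

    Returns the membership matrix, the realized per-transmitter counts, and
    any rule-application warnings.  Assignment order: rule sources first (in
    rule order), then remaining non-target transmitters in panel order; rule
    targets are built by :func:`apply_rules`.  A transmitter that is both a
    source and a target must be the target of an earlier rule than the one it
    sources, otherwise its source column would not exist yet.
    """
    rules = tuple(rules)
    target_order = []
    for rule in rules:
        if rule.target not in target_order:
            target_order.append(rule.target)
    for rule in rules:
        if rule.source in target_order:
            if target_order.index(rule.source) >= target_order.index(rule.target):
                raise ValueError(
                    f"rule {rule.label}: source {rule.source!r} is a rule target that "
                    "has not been built yet; reorder the rules"
                )

    n_cells = draw_population_size(panel.population_mean, panel.population_sd, rng)
    counts: dict[str, int] = {}
    for name, mean, sd in zip(panel.transmitters, panel.count_mean, panel.count_sd):
        counts[name] = draw_count(min(mean, float(n_cells)), sd, n_cells, rng)

    membership = np.zeros((n_cells, panel.n_transmitters), dtype=bool)
    targets = set(target_order)
    order: list[str] = []
    for rule in rules:  # sources first, in rule order
        if rule.source not in targets and rule.source not in order:
            order.append(rule.source)
    for name in panel.transmitters:
        if name not in targets and name not in order:
            order.append(name)
    for name in order:
        idx = assign_cells(n_cells, counts[name], rng)
        membership[idx, panel.index(name)] = True

    logs = apply_rules(membership, panel.transmitters, counts, rules, rng) if rules else []
    matrix = CellPopulationMatrix(membership, panel.transmitters)
    return matrix, counts, logs


def enumerate_rule_models(
    rule_pool: Sequence[Rule],
    max_rules: int,
    base_spec: ModelSpec,
) -> list[ModelSpec]:
    """All rule subsets of size 0..max_rules as model specs.

    Subsets are ordered by size then lexicographically by rule index within
    the pool; the empty subset is the unconstrained (independent) model.
    """
    if max_rules < 0:
        raise ValueError("max_rules must be >= 0")
    pool = tuple(rule_pool)
    specs: list[ModelSpec] = []
    for size in range(0, max_rules + 1):
        for combo in itertools.combinations(range(len(pool)), size):
            rules = tuple(pool[i] for i in combo)
            specs.append(replace(base_spec, rules=rules, label=""))
    return specs
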