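"""Independent-expression null model for transmitter coexpression.

The population is a cluster of ``N`` neurons (360 local interneurons of the
antennal lobe by default).  Each transmitter is expressed by a number of
cells drawn from a Normal distribution (rounded, clipped to ``[0, N]``) and
those cells are chosen uniformly at random, independently of every other
transmitter.  Pairwise coexpression is then summarised as directed ratios

    ratio[X -> Y] = |X-positive AND Y-positive| / |X-positive|

and a Monte Carlo run records the mean and standard deviation of each
directed ratio across iterations.  Under independence with fixed counts the
overlap |X AND Y| is Hypergeometric(N, n_X, n_Y), so E[ratio X->Y] = n_Y / N;
the Monte Carlo machinery exists so the same code path also supports
rule-constrained variants (see :mod:`coexsim.rules`).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransmitterPanel",
    "CellPopulationMatrix",
    "CoexpressionRatioTable",
    "ModelResult",
    "draw_count",
    "draw_population_size",
    "assign_cells",
    "simulate_population",
    "coexpression_ratios",
    "run_model",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero-point-five.

    Used for every count-valued rounding in the package so that e.g. a mean
    of 12.16 with zero spread always yields 12 cells.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TransmitterPanel:
    """Per-transmitter count distributions plus the population size.

    Parameters
    ----------
    transmitters
        Ordered, unique transmitter names.
    count_mean, count_sd
        Mean and standard deviation of the number of cells expressing each
        transmitter (cells per antennal lobe).
    population_mean, population_sd
        Size of the cell population the counts are drawn into.  A nonzero
        ``population_sd`` makes the population size itself stochastic, which
        supports constrained variants such as restricting the model to the
        ~170 GABAergic cells.
    """

    transmitters: tuple[str, ...]
    count_mean: tuple[float, ...]
    count_sd: tuple[float, ...]
    population_mean: float = 360.0
    population_sd: float = 0.0

    def __post_init__(self) -> None:
        names = tuple(self.transmitters)
        object.__setattr__(self, "transmitters", names)
        object.__setattr__(self, "count_mean", tuple(float(v) for v in self.count_mean))
        object.__setattr__(self, "count_sd", tuple(float(v) for v in self.count_sd))
        if len(set(names)) != len(names):
            raise ValueError("transmitter names must be unique")
        if not (len(names) == len(self.count_mean) == len(self.count_sd)):
            raise ValueError("transmitters, count_mean and count_sd must have equal length")
        if self.population_mean <= 0:
            raise ValueError("population_mean must be > 0")
        if self.population_sd < 0:
            raise ValueError("population_sd must be >= 0")
        for name, m, s in zip(names, self.count_mean, self.count_sd):
            if m < 0 or s < 0:
                raise ValueError(f"negative mean/sd for transmitter {name!r}")
            if m > self.population_mean:
                raise ValueError(
                    f"count_mean for {name!r} ({m}) exceeds population_mean "
                    f"({self.population_mean}); panel inconsistent with population"
                )

    @property
    def n_transmitters(self) -> int:
        return len(self.transmitters)

    def index(self, name: str) -> int:
        try:
            return self.transmitters.index(name)
        except ValueError:
            raise KeyError(f"unknown transmitter {name!r}") from None

    def subset(self, names: Sequence[str]) -> "TransmitterPanel":
        idx = [self.index(n) for n in names]
        return TransmitterPanel(
            transmitters=tuple(self.transmitters[i] for i in idx),
            count_mean=tuple(self.count_mean[i] for i in idx),
            count_sd=tuple(self.count_sd[i] for i in idx),
            population_mean=self.population_mean,
            population_sd=self.population_sd,
        )

    def with_population(self, mean: float, sd: float = 0.0) -> "TransmitterPanel":
        """Return a copy with a different population size (counts clipped there)."""
        return TransmitterPanel(
            transmitters=self.transmitters,
            count_mean=tuple(min(m, float(mean)) for m in self.count_mean),
            count_sd=self.count_sd,
            population_mean=float(mean),
            population_sd=float(sd),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transmitter": list(self.transmitters),
                "count_mean": list(self.count_mean),
                "count_sd": list(self.count_sd),
            }
        )


@dataclass(frozen=True)
class CellPopulationMatrix:
    """Boolean cells x transmitters membership table (one realization)."""

    membership: np.ndarray  # (n_cells, n_transmitters) bool
    transmitters: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.dtype != np.bool_:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("membership entries must be boolean")
            m = m.astype(bool)
        if m.ndim != 2 or m.shape[1] != len(self.transmitters):
            raise ValueError("membership must be n_cells x n_transmitters")
        object.__setattr__(self, "membership", m)
        object.__setattr__(self, "transmitters", tuple(self.transmitters))

    @property
    def n_cells(self) -> int:
        return self.membership.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """Per-transmitter positive-cell counts (column sums)."""
        return self.membership.sum(axis=0)

    def column(self, name: str) -> np.ndarray:
        return self.membership[:, self.transmitters.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.membership.astype(int), columns=list(self.transmitters))
        df.insert(0, "cell_id", np.arange(self.n_cells))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellPopulationMatrix":
        cols = [c for c in df.columns if c != "cell_id"]
        return cls(df[cols].to_numpy().astype(bool), tuple(cols))


@dataclass(frozen=True)
class CoexpressionRatioTable:
    """Directed coexpression ratios with their supporting counts.

    ``ratio[i, j]`` is the fraction of cells positive for transmitter ``i``
    that are also positive for ``j``; it is NaN (undefined) whenever
    ``source_count[i] == 0``.  ``overlap`` is symmetric.
    """

    transmitters: tuple[str, ...]
    overlap: np.ndarray       # (k, k) int
    source_count: np.ndarray  # (k,) int
    ratio: np.ndarray         # (k, k) float, NaN where undefined

    def ratio_of(self, source: str, target: str) -> float:
        i = self.transmitters.index(source)
        j = self.transmitters.index(target)
        return float(self.ratio[i, j])

    def overlap_of(self, source: str, target: str) -> int:
        i = self.transmitters.index(source)
        j = self.transmitters.index(target)
        return int(self.overlap[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.transmitters)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "source": self.transmitters[i],
                        "target": self.transmitters[j],
                        "source_count": int(self.source_count[i]),
                        "overlap": int(self.overlap[i, j]),
                        "ratio": float(self.ratio[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ModelResult:
    """Per-pair Monte Carlo mean and SD of the directed coexpression ratios."""

    transmitters: tuple[str, ...]
    mean_ratio: np.ndarray  # (k, k) float, NaN where never defined
    sd_ratio: np.ndarray    # (k, k) float
    n_defined: np.ndarray   # (k, k) int, iterations where the pair was defined
    n_iterations: int
    seed: int
    spec_digest: str = ""
    label: str = ""
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def mean_of(self, source: str, target: str) -> float:
        i = self.transmitters.index(source)
        j = self.transmitters.index(target)
        return float(self.mean_ratio[i, j])

    def sd_of(self, source: str, target: str) -> float:
        i = self.transmitters.index(source)
        j = self.transmitters.index(target)
        return float(self.sd_ratio[i, j])

    def to_records(self) -> list[dict]:
        recs = []
        k = len(self.transmitters)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                recs.append(
                    {
                        "source": self.transmitters[i],
                        "target": self.transmitters[j],
                        "mean": None if np.isnan(self.mean_ratio[i, j]) else float(self.mean_ratio[i, j]),
                        "sd": None if np.isnan(self.sd_ratio[i, j]) else float(self.sd_ratio[i, j]),
                        "n_defined": int(self.n_defined[i, j]),
                    }
                )
        return recs

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "seed": self.seed,
                "n_iterations": self.n_iterations,
                "spec_digest": self.spec_digest,
                "transmitters": list(self.transmitters),
                "pairs": self.to_records(),
                "warnings": list(self.warnings),
            },
            indent=2,
        )


def draw_count(mean: float, sd: float, population: int, rng: np.random.Generator) -> int:
    """Draw an integer cell count: round(Normal(mean, sd)) clipped to [0, population].

    With ``sd == 0`` this deterministically returns ``round(mean)``.
    """
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be >= 0")
    if population < 1:
        raise ValueError("population must be >= 1")
    if mean > population:
        raise ValueError(f"count mean {mean} exceeds population {population}")
    value = mean if sd == 0 else float(rng.normal(mean, sd))
    return int(np.clip(round_half_up(value), 0, population))


def draw_population_size(
    mean: float, sd: float, rng: np.random.Generator
) -> int:
    """Draw the population size itself: round(Normal(mean, sd)), floored at 1."""
    value = mean if sd == 0 else float(rng.normal(mean, sd))
    return max(1, round_half_up(value))


def assign_cells(n_cells: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Choose a uniformly random subset of exactly ``count`` cell indices."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if count > n_cells:
        raise ValueError(f"count {count} exceeds n_cells {n_cells}")
    return rng.permutation(n_cells)[:count]


def simulate_population(
    panel: TransmitterPanel, rng: np.random.Generator
) -> CellPopulationMatrix:
    """One realization of the independent-expression model."""
    from .rules import realize_population

    matrix, _, _ = realize_population(panel, (), rng)
    return matrix


def coexpression_ratios(matrix: CellPopulationMatrix) -> CoexpressionRatioTable:
    """Directed pairwise coexpression ratios of one realization.

    Pairs whose source set is empty are NaN and must be excluded from any
    downstream averaging.
    """
    m = matrix.membership.astype(np.int64)
    overlap = m.T @ m
    source = np.diag(overlap).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = overlap / source[:, None].astype(float)
    ratio[source == 0, :] = np.nan
    return CoexpressionRatioTable(
        transmitters=matrix.transmitters,
        overlap=overlap,
        source_count=source,
        ratio=ratio,
    )


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # Per-iteration stream derived from (seed, iteration) so results do not
    # depend on how iterations are chunked or parallelised.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(iteration)]))


def run_model(spec, n_iterations: int | None = None, seed: int | None = None) -> ModelResult:
    """Run a model specification for ``n_iterations`` Monte Carlo iterations.

    Parameters
    ----------
    spec
        A :class:`coexsim.rules.ModelSpec` (an empty rule list gives the
        independent-expression null model).
    n_iterations, seed
        Override the values stored on the spec.

    Per pair, iterations in which the source count is zero are skipped; the
    number of defined iterations is recorded in ``n_defined``.  Identical
    spec + seed yields a bit-identical result.
    """
    from .rules import ModelSpec, realize_population

    if not isinstance(spec, ModelSpec):
        raise TypeError("spec must be a ModelSpec")
    n_iterations = int(spec.n_iterations if n_iterations is None else n_iterations)
    seed = int(spec.seed if seed is None else seed)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    panel = spec.effective_panel()
    k = panel.n_transmitters
    total = np.zeros((k, k))
    total_sq = np.zeros((k, k))
    count = np.zeros((k, k), dtype=np.int64)
    warnings: list[str] = []

    for it in range(n_iterations):
        rng = _iteration_rng(seed, it)
        matrix, _, logs = realize_population(panel, spec.rules, rng)
        if logs and len(warnings) < 50:
            warnings.extend(f"iteration {it}: {msg}" for msg in logs)
        table = coexpression_ratios(matrix)
        defined = ~np.isnan(table.ratio)
        r = np.where(defined, table.ratio, 0.0)
        total += r
        total_sq += r * r
        count += defined

    with np.errstate(divide="ignore", invalid="ignore"):
        mean = total / count
        var = total_sq / count - mean * mean
    mean[count == 0] = np.nan
    var = np.clip(var, 0.0, None)
    var[count == 0] = np.nan
    return ModelResult(
        transmitters=panel.transmitters,
        mean_ratio=mean,
        sd_ratio=np.sqrt(var),
        n_defined=count,
        n_iterations=n_iterations,
        seed=seed,
        spec_digest=spec.digest(),
        label=spec.label,
        warnings=tuple(warnings[:50]),
    )
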