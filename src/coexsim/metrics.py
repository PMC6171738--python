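"""Standard deviation index (SDI) statistics for model-vs-data comparison.

For one directed pair, the SDI is a Z-score-like discrepancy

    SDI = |mean_model - mean_observed| / max(sd_model, sd_observed)

interpreted on a fixed scale: 0 means perfect consensus, values up to 1 mean
the model sits within one standard deviation of the data (replicates it
reasonably well), and values of 2 or more mean the model does not replicate
the data.  The per-pair SDIs are combined into a single model score by
weighting each pair by its observed prevalence,

    weighted SDI = sum_pairs SDI * (n_coexpressed / n_total),

so that pairs involving many cells dominate.  Models are ranked by weighted
SDI, and each is summarised relative to a reference model (normally the
independent-expression null) as

    % improvement = (1 - weighted_SDI / weighted_SDI_reference) * 100.

The absolute difference is used in the SDI so that per-pair discrepancies
accumulate rather than cancel in the weighted sum; the weights use the
*observed* overlap counts so they are identical for every model being
compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .population import ModelResult

__all__ = [
    "ObservedCoexpression",
    "SDIReport",
    "sdi",
    "interpret_sdi",
    "weighted_sdi",
    "percent_improvement",
    "compute_sdi_report",
    "rank_models",
]


@dataclass(frozen=True)
class ObservedCoexpression:
    """Observed directed ratios with replicate SDs and overlap counts.

    ``ratio_mean[i, j]`` / ``ratio_sd[i, j]`` describe the observed fraction
    of i-positive cells that are j-positive; NaN marks pairs never measured.
    ``overlap[i, j]`` is the observed number of coexpressing cells for the
    pair (used as the weight numerator).  Count statistics are optional
    context from the replicates the summary was computed from.
    """

    transmitters: tuple[str, ...]
    ratio_mean: np.ndarray
    ratio_sd: np.ndarray
    overlap: np.ndarray
    count_mean: np.ndarray | None = None
    count_sd: np.ndarray | None = None

    def index(self, name: str) -> int:
        return self.transmitters.index(name)

    def defined_pairs(self) -> list[tuple[str, str]]:
        """Directed pairs with a finite observed mean, SD and overlap."""
        pairs = []
        k = len(self.transmitters)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                if (
                    np.isfinite(self.ratio_mean[i, j])
                    and np.isfinite(self.ratio_sd[i, j])
                    and np.isfinite(self.overlap[i, j])
                ):
                    pairs.append((self.transmitters[i], self.transmitters[j]))
        return pairs


def sdi(mean_model: float, mean_observed: float, sd_model: float, sd_observed: float) -> float:
    """Standard deviation index for one pair (see module docstring)."""
    if sd_model < 0 or sd_observed < 0:
        raise ValueError("standard deviations must be >= 0")
    greatest = max(sd_model, sd_observed)
    diff = abs(mean_model - mean_observed)
    if greatest == 0:
        if diff == 0:
            return 0.0
        raise ValueError("SDI undefined: both SDs are zero and the means differ")
    return diff / greatest


def interpret_sdi(value: float) -> str:
    """The fixed interpretation scale for SDI values."""
    if value < 0:
        raise ValueError("SDI is non-negative")
    if value == 0:
        return "perfect consensus between model and data"
    if value <= 1:
        return "within one standard deviation; replicates the data reasonably well"
    if value < 2:
        return "between one and two standard deviations; marginal replication"
    return "two or more standard deviations; does not replicate the data"


def weighted_sdi(
    sdi_values: Sequence[float],
    overlap_counts: Sequence[float],
    n_total: float,
) -> float:
    """Prevalence-weighted sum of per-pair SDIs."""
    s = np.asarray(sdi_values, dtype=float)
    k = np.asarray(overlap_counts, dtype=float)
    if s.size == 0:
        raise ValueError("at least one pair is required")
    if s.shape != k.shape:
        raise ValueError("sdi_values and overlap_counts must have equal length")
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if np.isnan(k).any():
        raise ValueError("missing observed overlap count for a pair in pairs_used")
    if np.isnan(s).any():
        raise ValueError("missing SDI value for a pair in pairs_used")
    return float(np.sum(s * (k / n_total)))


def percent_improvement(weighted_sdi_x: float, weighted_sdi_reference: float) -> float:
    """Improvement of a model over the reference (positive = better)."""
    if weighted_sdi_reference <= 0:
        raise ValueError("reference weighted SDI must be > 0")
    return (1.0 - weighted_sdi_x / weighted_sdi_reference) * 100.0


@dataclass
class SDIReport:
    """Per-pair SDI table plus the weighted summary for one model."""

    label: str
    n_rules: int
    pairs: pd.DataFrame  # source, target, mean_model, mean_obs, sd_model, sd_obs, sdi, weight, interpretation
    weighted_sdi: float
    n_total: float
    excluded_pairs: tuple[tuple[str, str], ...] = ()
    reference_label: str | None = None
    reference_weighted_sdi: float | None = None
    percent_improvement: float | None = None

    def pairs_used(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["source"], self.pairs["target"]))

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n_rules": self.n_rules,
            "weighted_sdi": self.weighted_sdi,
            "n_total": self.n_total,
            "reference_label": self.reference_label,
            "reference_weighted_sdi": self.reference_weighted_sdi,
            "percent_improvement": self.percent_improvement,
            "excluded_pairs": [list(p) for p in self.excluded_pairs],
        }


def compute_sdi_report(
    result: ModelResult,
    observed: ObservedCoexpression,
    n_total: float = 360.0,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_rules: int = 0,
) -> SDIReport:
    """Score one model result against observed coexpression.

    ``pairs`` defaults to every directed pair with a finite observed mean,
    SD and overlap; pairs lacking an observed SD are excluded and listed on
    the report.  ``n_total`` is the population size used for the weights and
    is deliberately independent of the model's own population constraint so
    weighted SDIs are comparable across constrained and unconstrained models.
    """
    if pairs is None:
        pairs = observed.defined_pairs()
    excluded = []
    rows = []
    for source, target in pairs:
        io, jo = observed.index(source), observed.index(target)
        mean_obs = float(observed.ratio_mean[io, jo])
        sd_obs = float(observed.ratio_sd[io, jo])
        overlap = float(observed.overlap[io, jo])
        if not (np.isfinite(mean_obs) and np.isfinite(sd_obs) and np.isfinite(overlap)):
            excluded.append((source, target))
            continue
        mean_model = result.mean_of(source, target)
        sd_model = result.sd_of(source, target)
        if not np.isfinite(mean_model):
            excluded.append((source, target))
            continue
        value = sdi(mean_model, mean_obs, sd_model, sd_obs)
        rows.append(
            {
                "source": source,
                "target": target,
                "mean_model": mean_model,
                "mean_obs": mean_obs,
                "sd_model": sd_model,
                "sd_obs": sd_obs,
                "sdi": value,
                "weight": overlap / n_total,
                "interpretation": interpret_sdi(value),
            }
        )
    if not rows:
        raise ValueError("no usable pairs: every candidate pair lacks observed data")
    frame = pd.DataFrame(rows)
    total = weighted_sdi(
        frame["sdi"].to_numpy(), (frame["weight"] * n_total).to_numpy(), n_total
    )
    return SDIReport(
        label=result.label,
        n_rules=n_rules,
        pairs=frame,
        weighted_sdi=total,
        n_total=n_total,
        excluded_pairs=tuple(excluded),
    )


def rank_models(
    items: Sequence[tuple],
    observed: ObservedCoexpression,
    n_total: float = 360.0,
    pairs: Sequence[tuple[str, str]] | None = None,
    reference_label: str | None = None,
) -> list[SDIReport]:
    """Score and rank models against observed coexpression.

    ``items`` is a sequence of ``(spec, result)`` tuples.  Reports are sorted
    ascending by weighted SDI; ties break toward fewer rules, then label.
    Percent improvement is computed against the reference model (by label, or
    the first zero-rule spec if no label is given).
    """
    reports = []
    for spec, result in items:
        report = compute_sdi_report(
            result, observed, n_total=n_total, pairs=pairs, n_rules=spec.n_rules()
        )
        reports.append(report)

    reference = None
    if reference_label is not None:
        for report in reports:
            if report.label == reference_label:
                reference = report
                break
        if reference is None:
            raise ValueError(f"reference model {reference_label!r} not among items")
    else:
        for report in reports:
            if report.n_rules == 0:
                reference = report
                break
    if reference is not None and reference.weighted_sdi > 0:
        for report in reports:
            report.reference_label = reference.label
            report.reference_weighted_sdi = reference.weighted_sdi
            report.percent_improvement = percent_improvement(
                report.weighted_sdi, reference.weighted_sdi
            )
    reports.sort(key=lambda r: (r.weighted_sdi, r.n_rules, r.label))
    return reports
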