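"""Relative receptor expression from RT-qPCR Cq tables (delta-Ct, 2^-dCt).

The input layout mirrors the packaged quantification-cycle table: one row
per (receptor, RT-or-RT-minus) pair, one column per sample (three biological
replicates each for antennae, brain, medial and lateral cell clusters, plus
a genomic-DNA positive control / no-template control column).  Relative
expression of a receptor in a tissue is

    delta-Ct  = Cq(receptor) - Cq(reference gene)      per sample
    rel. expr = 2 ** -mean(delta-Ct over detectable samples)

with the 40S ribosomal protein S3 (RpS3) as the reference gene.

Nondetect conventions: a Cq of 0 means no amplification and a Cq at or
above the detection threshold (37 cycles by default) is treated as
nondetectable (ND); an ``x`` cell means the sample was not assayed.  ND
inputs propagate — no numeric delta-Ct is ever produced from an ND Cq — and
a tissue is reported ND only when every one of its samples is ND.  The
Mas-AT receptor was assayed at a 52 deg C annealing temperature, so its
reference is the matching RpS3 run at 52 deg C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "ND_THRESHOLD",
    "TISSUE_SAMPLES",
    "REFERENCE_GENE",
    "REFERENCE_OVERRIDES",
    "load_cq_csv",
    "packaged_cq_table",
    "write_cq_csv",
    "is_detectable",
    "delta_ct",
    "relative_expression",
    "summarize_tissue",
    "summarize_all",
]

ND_THRESHOLD = 37.0

TISSUE_SAMPLES: dict[str, tuple[str, ...]] = {
    "antennae": ("ANTa", "ANTb", "ANTc"),
    "brain": ("Ba", "Bb", "Bc"),
    "medial": ("Ma", "Mb", "Mc"),
    "lateral": ("La", "Lb", "Lc"),
}

REFERENCE_GENE = "RpS3"
# Mas-ATr primers anneal at 52 C; RpS3 was re-run at 52 C for that receptor.
REFERENCE_OVERRIDES = {"Mas-ATr": "RpS3-52C"}

# RT-minus samples of the 52 C RpS3 run whose high/noisy Cq values came from
# nondescript amplification noise, recorded as 0 when normalizing.
_RPS3_52C_NOISE_SAMPLES = ("ANTa", "Mb", "Genomic")


@dataclass(frozen=True)
class CqTable:
    """Cq values indexed by (receptor, rt) with one column per sample.

    Values are floats; NaN marks a not-assayed cell (``x`` in the CSV).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValueError("CqTable index must be (receptor, rt)")

    @property
    def receptors(self) -> list[str]:
        seen = []
        for receptor, _ in self.values.index:
            if receptor not in seen:
                seen.append(receptor)
        return seen

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, receptor: str, rt: str = "RT") -> pd.Series:
        try:
            return self.values.loc[(receptor, rt)]
        except KeyError:
            raise KeyError(f"no Cq row for receptor {receptor!r} ({rt})") from None

    def cq(self, receptor: str, sample: str, rt: str = "RT") -> float:
        return float(self.row(receptor, rt)[sample])


def load_cq_csv(path, zero_rt_minus_noise: bool = True) -> CqTable:
    """Read a Cq CSV in the packaged layout.

    ``x`` cells parse to NaN (not assayed).  With ``zero_rt_minus_noise``
    the noisy RT-minus cells of the 52 C reference-gene run are recorded as
    0, matching how they were treated in the source quantification.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("receptor", "rt"):
        if col not in df.columns:
            raise ValueError(f"Cq CSV missing required column {col!r}")
    df = df.set_index(["receptor", "rt"])
    parsed = df.apply(lambda s: pd.to_numeric(s.str.strip().replace("x", np.nan)))
    if (parsed.to_numpy() < 0).any():
        raise ValueError("Cq values must be >= 0")
    if zero_rt_minus_noise and ("RpS3-52C", "RT-") in parsed.index:
        for sample in _RPS3_52C_NOISE_SAMPLES:
            if sample in parsed.columns:
                parsed.loc[("RpS3-52C", "RT-"), sample] = 0.0
    return CqTable(parsed)


def packaged_cq_table(**kwargs) -> CqTable:
    """The packaged receptor Cq table."""
    return load_cq_csv(resources.files("coexsim.data").joinpath("observed_cq.csv"), **kwargs)


def write_cq_csv(table: CqTable, path) -> None:
    out = table.values.copy()
    out = out.map(lambda v: "x" if (isinstance(v, float) and math.isnan(v)) else f"{v:g}")
    out.reset_index().to_csv(path, index=False)


def is_detectable(cq: float, threshold: float = ND_THRESHOLD) -> bool:
    """A Cq is detectable when assayed, amplified (> 0) and below threshold."""
    return bool(np.isfinite(cq)) and 0.0 < cq < threshold


def delta_ct(ct_receptor: float, ct_reference: float, threshold: float = ND_THRESHOLD) -> float:
    """Per-sample delta-Ct; NaN (ND) if either input is nondetectable."""
    if not (is_detectable(ct_receptor, threshold) and is_detectable(ct_reference, threshold)):
        return float("nan")
    return float(ct_receptor - ct_reference)


def relative_expression(mean_delta_ct: float) -> float:
    """Relative expression 2^-dCt; monotone decreasing in delta-Ct."""
    return float(2.0 ** (-mean_delta_ct))


def summarize_tissue(
    table: CqTable,
    receptor: str,
    tissues: dict[str, tuple[str, ...]] | None = None,
    threshold: float = ND_THRESHOLD,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-tissue mean delta-Ct and relative expression for one receptor.

    ND samples are excluded from the tissue average; the tissue is flagged
    nondetectable only when all of its samples are ND (this exclude-then-veto
    behaviour is the default and the only ambiguity in the source protocol).
    """
    tissues = TISSUE_SAMPLES if tissues is None else tissues
    if reference is None:
        reference = REFERENCE_OVERRIDES.get(receptor, REFERENCE_GENE)
    receptor_row = table.row(receptor, "RT")
    reference_row = table.row(reference, "RT")  # KeyError if absent

    rows = []
    for tissue, samples in tissues.items():
        deltas = []
        for sample in samples:
            if sample not in receptor_row.index:
                raise KeyError(f"sample {sample!r} missing from Cq table")
            d = delta_ct(float(receptor_row[sample]), float(reference_row[sample]), threshold)
            if not math.isnan(d):
                deltas.append(d)
        detectable = bool(deltas)
        mean_d = float(np.mean(deltas)) if detectable else float("nan")
        rows.append(
            {
                "receptor": receptor,
                "tissue": tissue,
                "mean_delta_ct": mean_d,
                "rel_expr": relative_expression(mean_d) if detectable else float("nan"),
                "detectable": detectable,
                "n_samples_used": len(deltas),
            }
        )
    return pd.DataFrame(rows)


def summarize_all(
    table: CqTable,
    receptors: list[str] | None = None,
    tissues: dict[str, tuple[str, ...]] | None = None,
    threshold: float = ND_THRESHOLD,
) -> pd.DataFrame:
    """Relative expression for every (receptor, tissue) combination."""
    if receptors is None:
        skip = {REFERENCE_GENE, *REFERENCE_OVERRIDES.values()}
        receptors = [r for r in table.receptors if r not in skip]
    frames = [
        summarize_tissue(table, receptor, tissues=tissues, threshold=threshold)
        for receptor in receptors
    ]
    return pd.concat(frames, ignore_index=True)
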