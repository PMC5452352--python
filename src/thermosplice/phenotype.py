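"""Flowering-time temperature response and genotype comparisons.

The temperature response of a genotype is quantified per trait (days to
bolting, DTB, or rosette leaf number, RLN) as the ratio of the trait at low
ambient temperature (16C) over the trait at high temperature (25C): a
thermoresponsive genotype that flowers earlier when warm has a ratio above
1, a non-responder sits at 1.  Ratios are formed per replicate tray from
tray means (plants are never pooled across trays) and then averaged.
Genotypes are compared by a two-sided Student's (pooled-variance) t-test on
the per-tray ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PhenotypeRecord", "ResponseSummary", "response_ratio",
           "compare_response"]


@dataclass
class PhenotypeRecord:
    genotype: str
    condition: str  # 16C | 25C
    replicate_tray: int
    plant_id: str
    dtb: float  # days to bolting
    rln: float  # rosette leaf number

    def __post_init__(self) -> None:
        if self.dtb <= 0:
            raise ValueError("DTB must be positive")
        if self.rln < 0:
            raise ValueError("RLN must be nonnegative")


@dataclass
class ResponseSummary:
    genotype: str
    trait: str  # DTB | RLN
    per_replicate_ratios: list[float]
    mean_ratio: float


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def response_ratio(records, genotype: str, trait: str = "DTB",
                   cond_low: str = "16C", cond_high: str = "25C"
                   ) -> ResponseSummary:
    """Per-tray low/high-temperature trait ratio and its mean for a genotype."""
    if trait not in ("DTB", "RLN"):
        raise ValueError("trait must be DTB or RLN")
    col = trait.lower()
    df = _as_frame(records)
    df = df[df["genotype"] == genotype]
    if df.empty:
        raise ValueError(f"no records for genotype {genotype!r}")
    ratios = []
    for tray, grp in df.groupby("replicate_tray"):
        lo = grp.loc[grp["condition"] == cond_low, col]
        hi = grp.loc[grp["condition"] == cond_high, col]
        if lo.empty or hi.empty:
            raise ValueError(
                f"genotype {genotype}: tray {tray} lacks condition "
                f"{cond_low if lo.empty else cond_high}"
            )
        ratios.append(float(lo.mean() / hi.mean()))
    return ResponseSummary(genotype, trait, ratios, float(np.mean(ratios)))


def compare_response(summary_a: ResponseSummary,
                     summary_b: ResponseSummary) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance) on per-tray ratios."""
    a, b = summary_a.per_replicate_ratios, summary_b.per_replicate_ratios
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicate ratios per genotype")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
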