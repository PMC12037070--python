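"""Closed-form reporter quantification.

Miller units normalize beta-galactosidase activity (ONPG hydrolysis read at
A420) by reaction time, culture density (A600) and assay volume:

    MU = 1000 * A420 / (t_min * A600 * volume_mL)

with the standard 60-min reaction and 0.02 mL culture volume as defaults.
CFU survival fractions quantify gRNA/Cas9 targeting efficiency as the ratio
of induced to uninduced colony counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MillerReading", "SurvivalRecord", "miller_units",
           "survival_fraction", "miller_table"]


@dataclass(frozen=True)
class MillerReading:
    A420: float
    A600: float
    reaction_minutes: float = 60.0
    volume_factor: float = 0.02

    def __post_init__(self) -> None:
        if self.A600 <= 0:
            raise ValueError("A600 must be > 0")
        if self.reaction_minutes <= 0:
            raise ValueError("reaction_minutes must be > 0")
        if self.volume_factor <= 0:
            raise ValueError("volume_factor must be > 0")


@dataclass(frozen=True)
class SurvivalRecord:
    cfu_induced: int
    cfu_uninduced: int

    def __post_init__(self) -> None:
        if self.cfu_induced < 0 or self.cfu_uninduced < 0:
            raise ValueError("CFU counts must be >= 0")


def miller_units(r: MillerReading) -> float:
    """MU = 1000 * A420 / (minutes * A600 * volume)."""
    return 1000.0 * r.A420 / (r.reaction_minutes * r.A600 * r.volume_factor)


def survival_fraction(s: SurvivalRecord) -> float:
    """Induced/uninduced CFU ratio; undefined for zero uninduced counts."""
    if s.cfu_uninduced == 0:
        raise ValueError("cfu_uninduced must be > 0")
    return s.cfu_induced / s.cfu_uninduced


def miller_table(readings: pd.DataFrame, reaction_minutes: float = 60.0,
                 volume_factor: float = 0.02) -> pd.DataFrame:
    """Vectorized Miller units for a (sample, time_min, A420, A600) table.

    Per-timepoint MU are computed independently; a (mean, sd) aggregation
    over timepoints per sample is appended as attrs['summary'].
    """
    required = {"sample", "time_min", "A420", "A600"}
    if not required.issubset(readings.columns):
        raise ValueError(f"missing columns: {required - set(readings.columns)}")
    if (readings["A600"] <= 0).any():
        raise ValueError("A600 must be > 0")
    out = readings[["sample", "time_min"]].copy()
    out["MU"] = (1000.0 * readings["A420"]
                 / (reaction_minutes * readings["A600"] * volume_factor))
    summary = out.groupby("sample")["MU"].agg(["mean", "std"]).fillna(0.0)
    out.attrs["summary"] = summary
    return out
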