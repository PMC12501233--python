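"""Closed-form bioassay scores: relative mtDNA content from qPCR cycle
thresholds, ellipsoidal tumor volume from caliper measurements, and the
tumor inhibitory score comparing PKH label-retaining fractions normalized to
tumor volume between a drug regimen and its vehicle control."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "QpcrPair",
    "XenograftRecord",
    "relative_mtdna_content",
    "tumor_volume",
    "tumor_inhibitory_score",
    "score_cohort",
]

_CT_RANGE = (5.0, 40.0)


@dataclass(frozen=True)
class QpcrPair:
    """Mean cycle thresholds of the nuclear and mitochondrial qPCR targets
    (cycles).  Values outside the typical 5-40 cycle range trigger a warning
    but are accepted."""

    ct_nuclear: float
    ct_mito: float

    def __post_init__(self) -> None:
        for name in ("ct_nuclear", "ct_mito"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"QpcrPair.{name} must be finite, got {v}")
            if not _CT_RANGE[0] <= v <= _CT_RANGE[1]:
                warnings.warn(
                    f"QpcrPair.{name}={v} outside the typical Ct range {_CT_RANGE}",
                    stacklevel=3,
                )

    @classmethod
    def from_triplicates(
        cls, nuclear: Sequence[float], mito: Sequence[float]
    ) -> "QpcrPair":
        """Aggregate triplicate reactions by their mean Ct before ΔCt."""
        if len(nuclear) == 0 or len(mito) == 0:
            raise ValueError("triplicate lists must be non-empty")
        return cls(float(sum(nuclear) / len(nuclear)), float(sum(mito) / len(mito)))

    @property
    def delta_ct(self) -> float:
        """ΔCt = nuclear Ct − mitochondrial Ct."""
        return self.ct_nuclear - self.ct_mito


def relative_mtdna_content(pair: QpcrPair) -> float:
    """Relative mtDNA copy number: ``2 · 2^ΔCt`` with ΔCt = nuDNA Ct − mtDNA Ct.

    The factor 2 accounts for the two nuclear alleles per diploid genome.
    Strictly increasing in the nuclear Ct and decreasing in the
    mitochondrial Ct (an earlier mitochondrial crossing means more template).
    """
    return 2.0 * 2.0 ** pair.delta_ct


def tumor_volume(length: float, width: float) -> float:
    """Tumor volume (mm³) from caliper length and width (mm):
    ``0.5 · length · width²``."""
    if not (length > 0 and width > 0):
        raise ValueError(f"length and width must be > 0, got {length}, {width}")
    return 0.5 * length * width * width


@dataclass(frozen=True)
class XenograftRecord:
    """One tumor: PKH-high (CSC) and PKH-low (progenitor) percentages and
    volume, under a named drug regimen.  Volume may be given directly or
    derived from caliper length/width."""

    group: str
    pkh_hi: float
    pkh_lo: float
    tumor_length: Optional[float] = None
    tumor_width: Optional[float] = None
    tumor_volume: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pkh_hi", "pkh_lo"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if self.pkh_hi + self.pkh_lo > 100 + 1e-9:
            raise ValueError(
                f"pkh_hi + pkh_lo must be <= 100, got {self.pkh_hi + self.pkh_lo}"
            )
        if self.tumor_volume is None:
            if self.tumor_length is None or self.tumor_width is None:
                raise ValueError("provide tumor_volume or both tumor_length and tumor_width")
            object.__setattr__(
                self, "tumor_volume", tumor_volume(self.tumor_length, self.tumor_width)
            )

    @property
    def pkh_per_volume(self) -> float:
        """(%PKH_hi + %PKH_lo) / tumor volume — label-retaining burden per mm³."""
        if not self.tumor_volume or self.tumor_volume <= 0:
            raise DegenerateInputError(
                f"tumor volume must be > 0 to normalize PKH fractions "
                f"(group {self.group!r}, volume {self.tumor_volume})"
            )
        return (self.pkh_hi + self.pkh_lo) / self.tumor_volume


def tumor_inhibitory_score(
    control: XenograftRecord,
    test: XenograftRecord,
    *,
    control_anchored: bool = False,
) -> float:
    """Tumor inhibitory score of a drug regimen against vehicle control:

        score = (%PKHhi + %PKHlow)_control / V_control
              − (%PKHhi + %PKHlow)_test / V_test

    Higher scores mean the regimen reduced the slow-cycling (label-retaining)
    burden relative to control.  The raw difference is 0 for a test identical
    to control; ``control_anchored=True`` returns ``score + 1``, a display
    convention that places the control at 1.
    """
    score = control.pkh_per_volume - test.pkh_per_volume
    return score + 1.0 if control_anchored else score


def score_cohort(
    records: Iterable[XenograftRecord],
    control_group: str = "vehicle",
    *,
    control_anchored: bool = False,
) -> pd.DataFrame:
    """Score each regimen of a cohort against the control group.

    Per-group mean PKH fractions and volumes form one aggregate record per
    regimen; the score of each non-control regimen is computed against the
    control aggregate.  Returns one row per group with the aggregates and
    the score (control's own score is 0, or 1 when anchored).
    """
    df = pd.DataFrame(
        [
            {
                "group": r.group,
                "pkh_hi": r.pkh_hi,
                "pkh_lo": r.pkh_lo,
                "tumor_volume": r.tumor_volume,
            }
            for r in records
        ]
    )
    if df.empty:
        raise ValueError("empty cohort")
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not present in cohort")
    agg = df.groupby("group", sort=True).mean(numeric_only=True)
    means = {
        g: XenograftRecord(
            group=g,
            pkh_hi=row["pkh_hi"],
            pkh_lo=row["pkh_lo"],
            tumor_volume=row["tumor_volume"],
        )
        for g, row in agg.iterrows()
    }
    control = means[control_group]
    agg = agg.assign(
        n=df.groupby("group", sort=True).size(),
        score=[
            tumor_inhibitory_score(control, means[g], control_anchored=control_anchored)
            for g in agg.index
        ],
    )
    return agg.reset_index()
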