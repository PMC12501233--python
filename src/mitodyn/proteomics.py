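"""Enrichment filtering of label-free quantification (LFQ) proteomics.

Given per-protein triplicate intensities under serum-starved (SS) and
serum-fed (+S) conditions, proteins are first screened by identification
quality (at least two peptides, at least 10% sequence coverage, detected in
at least two of three replicates of at least one condition) and then
classified as

* ``exclusive_SS`` / ``exclusive_S`` — detected in ≥2/3 replicates of one
  condition and 0/3 of the other;
* ``up_SS`` — fold change SS/+S > 2 with a significant two-sided test;
* ``down_SS`` — fold change < 0.5 with a significant test;
* ``unchanged`` otherwise;
* ``not_evaluable`` when QC fails or the comparison is undefined.

The "enriched" set — the proteins fed into pathway analysis — is the union
of the SS-exclusive and SS-upregulated calls.

Fold change is the ratio of raw replicate means (matching the ">2-fold
change" convention); significance defaults to a two-sided Welch t-test on
log2 intensities with α = 0.05 and no multiple-testing correction.  An
intensity of exactly 0 is treated as a missing detection (the MaxQuant
output convention); both choices are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LfqRecord",
    "EnrichmentCall",
    "CATEGORIES",
    "qc_filter",
    "classify",
    "enriched_set",
    "classify_all",
]

CATEGORIES = ("exclusive_SS", "exclusive_S", "up_SS", "down_SS", "unchanged", "not_evaluable")

_REPLICATES = 3


def _clean(values: Sequence[Optional[float]], zero_as_missing: bool) -> tuple[Optional[float], ...]:
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(None)
            continue
        v = float(v)
        if v < 0:
            raise ValueError(f"intensities must be nonnegative, got {v}")
        out.append(None if (zero_as_missing and v == 0.0) else v)
    return tuple(out)


@dataclass(frozen=True)
class LfqRecord:
    """One protein's triplicate intensities in the two conditions plus the
    identification-quality metadata used by the QC filter.

    Missing detections are ``None``; use :meth:`from_intensities` to apply
    the zero-as-missing convention to raw matrix values.
    """

    protein_id: str
    intensities_ss: tuple[Optional[float], ...]
    intensities_s: tuple[Optional[float], ...]
    peptides: int
    coverage: float

    def __post_init__(self) -> None:
        for name in ("intensities_ss", "intensities_s"):
            vals = getattr(self, name)
            if len(vals) != _REPLICATES:
                raise ValueError(f"{name} must have exactly {_REPLICATES} replicates, got {len(vals)}")
            if any(v is not None and (not math.isfinite(v) or v < 0) for v in vals):
                raise ValueError(f"{name} values must be missing or finite nonnegative: {vals}")
        if self.peptides < 0:
            raise ValueError(f"peptides must be >= 0, got {self.peptides}")
        if not 0 <= self.coverage <= 100:
            raise ValueError(f"coverage must be a percentage in [0, 100], got {self.coverage}")

    @classmethod
    def from_intensities(
        cls,
        protein_id: str,
        intensities_ss: Sequence[Optional[float]],
        intensities_s: Sequence[Optional[float]],
        peptides: int,
        coverage: float,
        *,
        zero_as_missing: bool = True,
    ) -> "LfqRecord":
        return cls(
            protein_id=str(protein_id),
            intensities_ss=_clean(intensities_ss, zero_as_missing),
            intensities_s=_clean(intensities_s, zero_as_missing),
            peptides=int(peptides),
            coverage=float(coverage),
        )

    @property
    def valid_ss(self) -> tuple[float, ...]:
        return tuple(v for v in self.intensities_ss if v is not None)

    @property
    def valid_s(self) -> tuple[float, ...]:
        return tuple(v for v in self.intensities_s if v is not None)


@dataclass(frozen=True)
class EnrichmentCall:
    """Classification outcome for one protein.  ``fold_change`` and
    ``p_value`` are ``None`` for exclusives and non-evaluable records."""

    protein_id: str
    qc_pass: bool
    category: str
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category.startswith("exclusive") and self.fold_change is not None:
            raise ValueError("exclusive calls carry no fold change")
        if not self.qc_pass and self.category != "not_evaluable":
            raise ValueError("records failing QC must be not_evaluable")


def qc_filter(record: LfqRecord, *, min_peptides: int = 2, min_coverage: float = 10.0) -> bool:
    """Identification-quality screen: ≥ ``min_peptides`` peptides, ≥
    ``min_coverage``% sequence coverage, and detection in at least two of
    three replicates of at least one condition."""
    detected = max(len(record.valid_ss), len(record.valid_s))
    return (
        record.peptides >= min_peptides
        and record.coverage >= min_coverage
        and detected >= 2
    )


def classify(
    record: LfqRecord,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    *,
    min_peptides: int = 2,
    min_coverage: float = 10.0,
    log_ratio: bool = False,
) -> EnrichmentCall:
    """Classify one protein.

    Exclusivity (≥2/3 detections in one condition, 0/3 in the other) is
    decided before any ratio; otherwise the fold change SS/+S is computed on
    raw replicate means (or as ``2**(mean log2 difference)`` with
    ``log_ratio=True``) and tested with a two-sided Welch t-test on log2
    intensities.  Calling ``up_SS``/``down_SS`` requires both the fold-change
    threshold and ``p < alpha``; when a test is impossible (fewer than two
    valid replicates on a side) a threshold-crossing ratio cannot be
    confirmed and the record is ``not_evaluable``.
    """
    if not qc_filter(record, min_peptides=min_peptides, min_coverage=min_coverage):
        return EnrichmentCall(record.protein_id, False, "not_evaluable", reason="qc_fail")

    ss, s = record.valid_ss, record.valid_s
    if len(ss) >= 2 and len(s) == 0:
        return EnrichmentCall(record.protein_id, True, "exclusive_SS")
    if len(s) >= 2 and len(ss) == 0:
        return EnrichmentCall(record.protein_id, True, "exclusive_S")
    if len(ss) == 0 or len(s) == 0:
        # qc guaranteed >=2 detections on one side, so this side has 1 on the
        # other: too few for exclusivity's "0 of 3" and for any ratio test
        return EnrichmentCall(record.protein_id, True, "not_evaluable", reason="single_detection")

    mean_s = float(np.mean(s))
    mean_ss = float(np.mean(ss))
    if mean_s == 0.0:
        return EnrichmentCall(record.protein_id, True, "not_evaluable", reason="zero_denominator")
    if any(v <= 0 for v in ss + s):
        return EnrichmentCall(record.protein_id, True, "not_evaluable", reason="nonpositive_intensity")

    if log_ratio:
        fc = float(2.0 ** (np.mean(np.log2(ss)) - np.mean(np.log2(s))))
    else:
        fc = mean_ss / mean_s

    p: Optional[float] = None
    if len(ss) >= 2 and len(s) >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(np.log2(ss), np.log2(s), equal_var=False)
        p = float(res.pvalue)

    crosses = fc > fc_up or fc < fc_down
    if crosses and p is None:
        return EnrichmentCall(
            record.protein_id, True, "not_evaluable", fold_change=fc,
            reason="insufficient_replicates_for_test",
        )
    if fc > fc_up and p is not None and not math.isnan(p) and p < alpha:
        return EnrichmentCall(record.protein_id, True, "up_SS", fold_change=fc, p_value=p)
    if fc < fc_down and p is not None and not math.isnan(p) and p < alpha:
        return EnrichmentCall(record.protein_id, True, "down_SS", fold_change=fc, p_value=p)
    return EnrichmentCall(record.protein_id, True, "unchanged", fold_change=fc, p_value=p)


def classify_all(records: Iterable[LfqRecord], **kwargs) -> list[EnrichmentCall]:
    """Classify every record; raises on duplicate protein identifiers."""
    seen: set[str] = set()
    calls = []
    for rec in records:
        if rec.protein_id in seen:
            raise ValueError(f"duplicate protein_id {rec.protein_id!r}")
        seen.add(rec.protein_id)
        calls.append(classify(rec, **kwargs))
    return calls


def enriched_set(records: Iterable[LfqRecord], **kwargs) -> set[str]:
    """Identifiers of the SS-enriched proteins: the union of ``exclusive_SS``
    and ``up_SS`` calls among QC-passing records."""
    return {
        c.protein_id
        for c in classify_all(records, **kwargs)
        if c.category in ("exclusive_SS", "up_SS")
    }
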