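"""Variant-level hard filters, quality filters and the diploidy (VAF) check.

Thresholds follow the GATK hard-filtering recipe used by the in-house calling
pipeline: SNVs fail on QD < 2.0, MQ < 40.0, MQRankSum < -12.5 or
ReadPosRankSum < -8.0; INDELs fail on QD < 2.0 or ReadPosRankSum < -20.0.
Downstream quality filtering requires FILTER == PASS, DP > 10 and QUAL > 100
(all comparisons strict, exactly as stated).  A missing metric never fails
its test (GATK convention).

The diploidy check approximates the caller's ploidy criterion as a
configurable minimum variant-allele fraction for heterozygous calls; the
threshold is not part of the published protocol (only an 18%-VAF failing
example is), so it defaults to 0.2 and is excluded from the quantitative
acceptance surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .variantcore import INDEL, SNV, NormalizedVariant

log = logging.getLogger(__name__)

# failure codes
SNP_QD = "SNP_QD"
SNP_MQ = "SNP_MQ"
SNP_MQRankSum = "SNP_MQRankSum"
SNP_ReadPosRankSum = "SNP_ReadPosRankSum"
INDEL_QD = "INDEL_QD"
INDEL_ReadPosRankSum = "INDEL_ReadPosRankSum"
NOT_PASS_FLAG = "NOT_PASS_FLAG"
LOW_DP = "LOW_DP"
LOW_QUAL = "LOW_QUAL"
LOW_VAF = "LOW_VAF"

ALL_CODES = (SNP_QD, SNP_MQ, SNP_MQRankSum, SNP_ReadPosRankSum,
             INDEL_QD, INDEL_ReadPosRankSum, NOT_PASS_FLAG,
             LOW_DP, LOW_QUAL, LOW_VAF)

HARD_CODES = frozenset((SNP_QD, SNP_MQ, SNP_MQRankSum, SNP_ReadPosRankSum,
                        INDEL_QD, INDEL_ReadPosRankSum))
QUALITY_CODES = frozenset((NOT_PASS_FLAG, LOW_DP, LOW_QUAL))


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")

    @classmethod
    def from_reasons(cls, reasons: Iterable[str]) -> "FilterVerdict":
        rs = tuple(dict.fromkeys(reasons))  # stable dedupe
        return cls(passed=not rs, reasons=rs)


_SNV_RULES = ((SNP_QD, "QD", 2.0), (SNP_MQ, "MQ", 40.0),
              (SNP_MQRankSum, "MQRankSum", -12.5),
              (SNP_ReadPosRankSum, "ReadPosRankSum", -8.0))
_INDEL_RULES = ((INDEL_QD, "QD", 2.0),
                (INDEL_ReadPosRankSum, "ReadPosRankSum", -20.0))


def hard_filter(v: NormalizedVariant) -> FilterVerdict:
    """GATK-style hard filtering by variant type; missing metrics pass."""
    rules = _SNV_RULES if v.vtype == SNV else _INDEL_RULES
    reasons = []
    for code, metric, cutoff in rules:
        value = v.info.get(metric)
        if value is not None and value < cutoff:
            reasons.append(code)
    return FilterVerdict.from_reasons(reasons)


def quality_filter(
    v: NormalizedVariant, min_dp: float = 10, min_qual: float = 100
) -> FilterVerdict:
    """Require FILTER == PASS, DP > min_dp and QUAL > min_qual (strict)."""
    reasons = []
    if (v.filter or "PASS") not in ("PASS", "."):
        reasons.append(NOT_PASS_FLAG)
    dp = v.info.get("DP")
    if dp is not None and not dp > min_dp:
        reasons.append(LOW_DP)
    if v.qual is not None and not v.qual > min_qual:
        reasons.append(LOW_QUAL)
    return FilterVerdict.from_reasons(reasons)


def diploidy_check(v: NormalizedVariant, min_vaf: float = 0.2) -> FilterVerdict:
    """Fail with LOW_VAF when the variant-allele fraction is below min_vaf.

    An absent VAF passes with a warning (the check is vacuous without
    allele depths).
    """
    if v.vaf is None:
        log.warning("no VAF for %s; diploidy check skipped", v)
        return FilterVerdict(True)
    if v.vaf < min_vaf:
        return FilterVerdict.from_reasons([LOW_VAF])
    return FilterVerdict(True)


def combine(*verdicts: FilterVerdict) -> FilterVerdict:
    """Order-independent union of failure reasons."""
    reasons: list[str] = []
    for v in verdicts:
        reasons.extend(v.reasons)
    return FilterVerdict.from_reasons(sorted(set(reasons), key=ALL_CODES.index))


def evaluate(
    v: NormalizedVariant,
    *,
    use_hard: bool = True,
    use_quality: bool = True,
    use_diploidy: bool = False,
    min_dp: float = 10,
    min_qual: float = 100,
    min_vaf: float = 0.2,
) -> FilterVerdict:
    """Combined verdict of the enabled filters (pure function of the record)."""
    parts = []
    if use_hard:
        parts.append(hard_filter(v))
    if use_quality:
        parts.append(quality_filter(v, min_dp=min_dp, min_qual=min_qual))
    if use_diploidy:
        parts.append(diploidy_check(v, min_vaf=min_vaf))
    return combine(*parts)
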