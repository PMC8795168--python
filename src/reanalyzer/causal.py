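"""Causal-variant detection audit and yield arithmetic.

Given a truth table of known causal variants (per solved case) and the
per-sample call sets of a pipeline, reports which causal variants the
pipeline detects.  SNVs must match exactly; INDELs match on reference-span
overlap, so a representation-shifted deletion still counts as the same
variant.  Missed records carry the most specific reason derivable from the
raw call set: a present-but-filtered call reports the failing filter class,
a record outside the active target regions reports that, anything else is
absent from the calls.

Percentage helpers implement the two reporting conventions used for audit
figures: detection efficiency truncates at the printed precision (never
overstating detection), diagnostic yield rounds half-up.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from . import qc_filters
from .annotation import AnnotatedVariant
from .variantcore import (INDEL, SNV, NormalizedVariant, TargetRegions,
                          VariantKey, in_regions, match, normalize_chrom,
                          variant_type)

log = logging.getLogger(__name__)

FOUND = "found"
MISSED = "missed"

ABSENT_FROM_CALLS = "absent_from_calls"
HARD_FILTER_FAIL = "hard_filter_fail"
LOW_QUAL_DP = "low_qual_dp"
LOW_VAF = "low_vaf"
OUTSIDE_REGIONS = "outside_regions"


@dataclass
class CausalRecord:
    """One known causal variant from the diagnostic records."""

    sample_id: str
    gene_symbol: Optional[str] = None
    transcript_id: Optional[str] = None
    hgvs_c: Optional[str] = None
    vtype: Optional[str] = None
    zygosity: Optional[str] = None
    genomic_key: Optional[VariantKey] = None

    def __post_init__(self) -> None:
        if self.genomic_key is None and not (self.transcript_id and self.hgvs_c):
            raise ValueError(
                "causal record needs a genomic key or (transcript, hgvs_c)")
        if self.genomic_key is not None and self.vtype is None:
            self.vtype = variant_type(self.genomic_key.ref,
                                      self.genomic_key.alt)[0]


@dataclass
class CausalDetection:
    record: CausalRecord
    status: str  # found | missed
    miss_reason: Optional[str] = None
    matched_key: Optional[VariantKey] = None
    homopolymer: bool = False


@dataclass
class DetectionReport:
    detections: list[CausalDetection]
    unresolved: list[CausalRecord] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.detections)

    @property
    def n_found(self) -> int:
        return sum(d.status == FOUND for d in self.detections)

    @property
    def efficiency_pct(self) -> float:
        return efficiency(self.n_found, self.n_total)

    def summary(self) -> dict:
        reasons: dict[str, int] = {}
        for d in self.detections:
            if d.status == MISSED:
                reasons[d.miss_reason] = reasons.get(d.miss_reason, 0) + 1
        return {
            "n_total": self.n_total,
            "n_found": self.n_found,
            "n_unresolved": len(self.unresolved),
            "efficiency_pct": self.efficiency_pct,
            "miss_reasons": reasons,
        }


def _strip_version(accession: Optional[str]) -> Optional[str]:
    return accession.split(".")[0] if accession else accession


def _pseudo_variant(key: VariantKey) -> NormalizedVariant:
    vtype, mnv = variant_type(key.ref, key.alt)
    return NormalizedVariant(
        chrom=normalize_chrom(key.chrom), pos=key.pos, ref=key.ref,
        alt=key.alt, vtype=vtype, qual=None, filter="PASS", info={},
        vaf=None, sample_id=None, mnv=mnv)


def _is_homopolymer_context(reference, v: NormalizedVariant,
                            run: int = 4) -> bool:
    """Run of >= `run` identical bases adjacent to the variant locus."""
    if reference is None:
        return False
    s = v.span
    try:
        left = reference.fetch(s.chrom, max(0, s.start - run), s.start)
        right = reference.fetch(s.chrom, s.end, s.end + run)
    except Exception:  # missing context is informational only
        return False
    for flank in (left, right):
        if len(flank) >= run and len(set(flank)) == 1:
            return True
    return False


def find_causal(
    records: Sequence[CausalRecord],
    calls: Mapping[str, Sequence[NormalizedVariant]],
    *,
    annotations: Optional[Mapping[str, Sequence[AnnotatedVariant]]] = None,
    regions: Optional[TargetRegions] = None,
    use_hard_filter: bool = True,
    use_quality_filter: bool = True,
    use_diploidy: bool = False,
    min_vaf: float = 0.2,
    reference=None,
) -> DetectionReport:
    """Audit detection of known causal variants in a pipeline's call sets.

    A record is found when a call in its sample matches it — exactly for
    SNVs, by span overlap for INDELs — and that call passes the enabled
    filters.  ``annotations`` enables fallback matching of records that carry
    no genomic key, by (versionless transcript accession, HGVS c.) string
    equality; records resolvable by neither route are reported unresolved and
    excluded from the denominator.
    """
    detections: list[CausalDetection] = []
    unresolved: list[CausalRecord] = []
    for rec in records:
        sample_calls = list(calls.get(rec.sample_id, ()))
        if regions is not None:
            sample_calls = [c for c in sample_calls if in_regions(c, regions)]
        target: Optional[NormalizedVariant] = None
        matched: list[NormalizedVariant] = []
        if rec.genomic_key is not None:
            target = _pseudo_variant(rec.genomic_key)
            mode = "exact" if target.vtype == SNV else "overlap_indel"
            matched = [c for c in sample_calls if match(target, c, mode)]
        elif annotations is not None:
            want = (_strip_version(rec.transcript_id), rec.hgvs_c)
            for av in annotations.get(rec.sample_id, ()):
                for ann in av.annotations:
                    if (_strip_version(ann.transcript_id), ann.hgvs_c) == want:
                        matched.append(av.variant)
                        target = av.variant
                        break
        else:
            unresolved.append(rec)
            continue

        homopoly = (_is_homopolymer_context(reference, target)
                    if target is not None else False)
        if matched:
            verdicts = [qc_filters.evaluate(
                c, use_hard=use_hard_filter, use_quality=use_quality_filter,
                use_diploidy=use_diploidy, min_vaf=min_vaf) for c in matched]
            passing = [c for c, v in zip(matched, verdicts) if v.passed]
            if passing:
                detections.append(CausalDetection(
                    rec, FOUND, matched_key=passing[0].key,
                    homopolymer=homopoly))
                continue
            reasons = {r for v in verdicts for r in v.reasons}
            if qc_filters.LOW_VAF in reasons:
                why = LOW_VAF
            elif reasons & qc_filters.HARD_CODES:
                why = HARD_FILTER_FAIL
            else:
                why = LOW_QUAL_DP
            detections.append(CausalDetection(
                rec, MISSED, miss_reason=why, matched_key=matched[0].key,
                homopolymer=homopoly))
        else:
            why = ABSENT_FROM_CALLS
            if (regions is not None and target is not None
                    and rec.genomic_key is not None):
                s = target.span
                if not regions.overlaps(s.chrom, s.start, s.end):
                    why = OUTSIDE_REGIONS
            detections.append(CausalDetection(
                rec, MISSED, miss_reason=why, homopolymer=homopoly))
    return DetectionReport(detections=detections, unresolved=unresolved)


# ---------------------------------------------------------------------------
# Percentage arithmetic
# ---------------------------------------------------------------------------

def _round_pct(x: float, decimals: int, mode: str) -> float:
    q = Decimal(1).scaleb(-decimals)
    rounding = {"half_up": ROUND_HALF_UP, "floor": ROUND_FLOOR}[mode]
    return float(Decimal(repr(x)).quantize(q, rounding=rounding))


def efficiency(n_found: int, n_total: int, decimals: int = 2,
               mode: str = "floor") -> float:
    """Detection efficiency as a percentage, truncated at ``decimals``.

    Truncation (never rounding up) is the audit convention: a reported
    99.74% means at least that fraction was detected.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_found <= n_total:
        raise ValueError("need 0 <= n_found <= n_total")
    return _round_pct(100.0 * n_found / n_total, decimals, mode)


def diagnostic_yield(n_solved: int, n_total: int, decimals: int = 1,
                     mode: str = "half_up") -> float:
    """Diagnostic yield as a percentage, rounded half-up at ``decimals``."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_solved <= n_total:
        raise ValueError("need 0 <= n_solved <= n_total")
    return _round_pct(100.0 * n_solved / n_total, decimals, mode)


@dataclass(frozen=True)
class YieldSummary:
    label: str
    n_solved: int
    n_total: int
    decimals: int = 1
    mode: str = "half_up"

    @property
    def yield_pct(self) -> float:
        return diagnostic_yield(self.n_solved, self.n_total,
                                decimals=self.decimals, mode=self.mode)


# ---------------------------------------------------------------------------
# Truth-table I/O
# ---------------------------------------------------------------------------

_TRUTH_FIELDS = ("sample", "gene", "transcript", "hgvs_c", "chrom", "pos",
                 "ref", "alt", "vtype", "zygosity")


def read_causal_table(path) -> list[CausalRecord]:
    """Read the causal truth TSV (genomic columns optional)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = None
            if row.get("chrom") and row.get("pos"):
                key = VariantKey(normalize_chrom(row["chrom"]),
                                 int(row["pos"]), row["ref"], row["alt"])
            out.append(CausalRecord(
                sample_id=row["sample"],
                gene_symbol=row.get("gene") or None,
                transcript_id=row.get("transcript") or None,
                hgvs_c=row.get("hgvs_c") or None,
                vtype=row.get("vtype") or None,
                zygosity=row.get("zygosity") or None,
                genomic_key=key,
            ))
    return out


def write_causal_table(records: Sequence[CausalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_FIELDS)
        for r in records:
            k = r.genomic_key
            w.writerow([
                r.sample_id, r.gene_symbol or "", r.transcript_id or "",
                r.hgvs_c or "", k.chrom if k else "", k.pos if k else "",
                k.ref if k else "", k.alt if k else "", r.vtype or "",
                r.zygosity or "",
            ])
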