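"""Variant representation, normalization, matching and target-region arithmetic.

Coordinate conventions
----------------------
Internal intervals are 0-based half-open (the BED convention); VCF positions
are 1-based and converted on ingest.  ``NormalizedVariant.pos`` stays 1-based
so records round-trip to VCF unchanged; ``NormalizedVariant.span`` exposes the
0-based half-open footprint on the reference used for interval arithmetic.

Normalization follows the vt/bcftools convention: multiallelic records are
decomposed, shared trailing then leading bases are trimmed, and INDELs are
shifted to their left-most equivalent representation against a reference
context.  Without a reference, a trim-only normalization is applied and a
warning logged (shift-equivalent INDELs may then fail to match).

Chromosome-name dialects ("chr1" vs "1") are unified by stripping a leading
"chr" (configurable via :func:`normalize_chrom`).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

log = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "INDEL"

_BASES = set("ACGTN")


class SymbolicAlleleError(ValueError):
    """Raised when an alternate allele is symbolic (<DEL>, breakends, ...)."""


def normalize_chrom(chrom: str, strip_chr: bool = True) -> str:
    """Unify chromosome-name dialects; by default ``chr1`` -> ``1``."""
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# Intervals and target regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


class TargetRegions:
    """An ordered, merged set of targeted genomic intervals.

    The representation is always merged: no two stored intervals on the same
    chromosome overlap or abut.  ``padded`` records whether :meth:`pad` has
    been applied and ``pad_bp`` with which width.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        padded: bool = False,
        pad_bp: int = 1000,
    ) -> None:
        if pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            self._merge(sorted(intervals, key=lambda iv: (iv.chrom, iv.start)))
        )
        self.padded = padded
        self.pad_bp = pad_bp
        # per-chromosome sorted (starts, ends) for O(log n) overlap queries
        self._index: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = self._index.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    @staticmethod
    def _merge(ivs: Sequence[GenomicInterval]) -> Iterator[GenomicInterval]:
        cur: Optional[GenomicInterval] = None
        for iv in ivs:
            if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
                if iv.end > cur.end:
                    cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            else:
                if cur is not None:
                    yield cur
                cur = iv
        if cur is not None:
            yield cur

    # -- queries ------------------------------------------------------------
    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval (partial counts)."""
        idx = self._index.get(normalize_chrom(chrom))
        if idx is None:
            return False
        starts, ends = idx
        i = bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    # -- derivation ---------------------------------------------------------
    def pad(self, pad_bp: Optional[int] = None) -> "TargetRegions":
        """Extend every interval by ``pad_bp`` on both sides (clip at 0)."""
        bp = self.pad_bp if pad_bp is None else pad_bp
        if bp < 0:
            raise ValueError("pad_bp must be >= 0")
        return TargetRegions(
            (GenomicInterval(iv.chrom, max(0, iv.start - bp), iv.end + bp)
             for iv in self.intervals),
            padded=True,
            pad_bp=bp,
        )

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetRegions) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return (f"TargetRegions(n={len(self.intervals)}, "
                f"padded={self.padded}, pad_bp={self.pad_bp})")

    # -- BED round-trip ------------------------------------------------------
    @classmethod
    def from_bed(cls, path) -> "TargetRegions":
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
                ivs.append(GenomicInterval(
                    normalize_chrom(parts[0]), int(parts[1]), int(parts[2])))
        return cls(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def pad_regions(regions: TargetRegions, pad_bp: int) -> TargetRegions:
    """Functional alias for :meth:`TargetRegions.pad`."""
    return regions.pad(pad_bp)


# ---------------------------------------------------------------------------
# Variant records
# ---------------------------------------------------------------------------

class VariantKey(NamedTuple):
    """Exact-match identity of a normalized variant."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class RawVariantRecord:
    """One VCF data line prior to normalization (possibly multiallelic)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: Sequence[str]
    qual: Optional[float] = None
    filter: str = "PASS"
    info_metrics: Mapping[str, float] = field(default_factory=dict)
    sample_gt: Optional[str] = None
    allele_depths: Optional[Sequence[int]] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF pos must be >= 1")
        if not self.ref or not set(self.ref.upper()) <= _BASES:
            raise ValueError(f"invalid REF allele {self.ref!r}")


@dataclass(eq=False)
class NormalizedVariant:
    """One allele-decomposed, trimmed, left-aligned variant call."""

    __slots__ = ("chrom", "pos", "ref", "alt", "vtype", "qual", "filter",
                 "info", "vaf", "sample_id", "mnv")

    chrom: str
    pos: int  # 1-based, post-normalization
    ref: str
    alt: str
    vtype: str
    qual: Optional[float]
    filter: str
    info: Mapping[str, float]
    vaf: Optional[float]
    sample_id: Optional[str]
    mnv: bool

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> GenomicInterval:
        """0-based half-open reference footprint.

        Insertions span the two anchor bases flanking the insertion point so
        that boundary overlap is well-defined.
        """
        start = self.pos - 1
        if len(self.alt) > len(self.ref) and self.alt.startswith(self.ref):
            return GenomicInterval(self.chrom, start, start + len(self.ref) + 1)
        return GenomicInterval(self.chrom, start, start + len(self.ref))

    def __repr__(self) -> str:
        return (f"NormalizedVariant({self.chrom}:{self.pos} "
                f"{self.ref}>{self.alt} {self.vtype})")


def variant_type(ref: str, alt: str) -> tuple[str, bool]:
    """Return (vtype, is_mnv) under the length rule.

    SNV iff both alleles are single bases; everything else (including
    non-trimmable multi-nucleotide substitutions) is INDEL, with the MNV case
    flagged.
    """
    if len(ref) == 1 and len(alt) == 1:
        return SNV, False
    return INDEL, len(ref) == len(alt)


def classify_type(v: NormalizedVariant) -> str:
    """Variant type under the length rule (SNV iff 1-bp ref and alt)."""
    return variant_type(v.ref, v.alt)[0]


# ---------------------------------------------------------------------------
# Reference context
# ---------------------------------------------------------------------------

class DictReference:
    """In-memory reference: a mapping of chromosome name -> sequence string."""

    def __init__(self, seqs: Mapping[str, str]) -> None:
        self._seqs = {normalize_chrom(c): s.upper() for c, s in seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of the reference sequence."""
        seq = self._seqs.get(normalize_chrom(chrom))
        if seq is None:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        return seq[max(0, start):end]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt == "."


def _normalize_allele(chrom, pos, ref, alt, reference, window):
    """Trim + left-align a single (pos, ref, alt); returns (pos, ref, alt)."""
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise ValueError(f"REF == ALT at {chrom}:{pos}")
    left_limit = max(1, pos - window)
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            trimmed = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                # an allele emptied: left-extend with the preceding base, or
                # re-anchor at the chromosome start where none exists
                if reference is None:
                    log.warning(
                        "no reference context at %s:%s; trim-only "
                        "normalization (left-alignment skipped)", chrom, pos)
                    raise _TrimOnly()
                if pos <= 1:
                    ref, alt = ref + trimmed, alt + trimmed
                    break
                if pos <= left_limit:
                    raise ValueError(
                        f"reference context exhausted left-aligning {chrom}:{pos}")
                b = reference.fetch(chrom, pos - 2, pos - 1).upper()
                if not b:
                    raise ValueError(
                        f"missing reference context at {chrom}:{pos - 1}")
                pos -= 1
                ref, alt = b + ref, b + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class _TrimOnly(Exception):
    """Internal: signals fall-back to trim-only normalization."""


def _trim_only(pos, ref, alt):
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    return pos, ref, alt


def normalize(
    record: RawVariantRecord,
    reference=None,
    window: int = 200,
) -> list[NormalizedVariant]:
    """Decompose, trim and left-align a raw VCF record.

    Returns one :class:`NormalizedVariant` per (non-spanning) alternate
    allele.  ``reference`` is any object with a ``fetch(chrom, start0, end0)``
    method covering the record's span plus up to ``window`` bp of left flank;
    when absent, trim-only normalization is applied.  VAF is computed as
    alt depth / total depth when allele depths are present.

    Raises :class:`SymbolicAlleleError` for symbolic/breakend alternates.
    """
    chrom = normalize_chrom(record.chrom)
    out: list[NormalizedVariant] = []
    ad = record.allele_depths
    total_depth = sum(ad) if ad else 0
    for i, alt in enumerate(record.alt):
        if alt == "*":
            log.debug("skipping spanning-deletion allele at %s:%s", chrom, record.pos)
            continue
        if _is_symbolic(alt) or not set(alt.upper()) <= _BASES:
            raise SymbolicAlleleError(
                f"symbolic allele {alt!r} at {chrom}:{record.pos}")
        try:
            pos, ref, nalt = _normalize_allele(
                chrom, record.pos, record.ref, alt, reference, window)
        except _TrimOnly:
            pos, ref, nalt = _trim_only(record.pos, record.ref.upper(), alt.upper())
        vtype, mnv = variant_type(ref, nalt)
        vaf = None
        if ad and total_depth > 0 and len(ad) > i + 1:
            vaf = ad[i + 1] / total_depth
        out.append(NormalizedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=nalt, vtype=vtype,
            qual=record.qual, filter=record.filter or "PASS",
            info=dict(record.info_metrics), vaf=vaf,
            sample_id=record.sample_id, mnv=mnv,
        ))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

EXACT = "exact"
OVERLAP_INDEL = "overlap_indel"
MATCH_MODES = (EXACT, OVERLAP_INDEL)


def match(a: NormalizedVariant, b: NormalizedVariant, mode: str = EXACT) -> bool:
    """Pairwise variant identity.

    ``exact``: equality of (chrom, pos, ref, alt).  ``overlap_indel``: exact
    for SNV pairs; INDEL pairs are the same variant when their reference spans
    share at least one base (insertion spans include both flanking anchors).
    Symmetric in both modes.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    if a.key == b.key:
        return True
    if mode == OVERLAP_INDEL and a.vtype == INDEL and b.vtype == INDEL:
        return a.span.overlaps(b.span)
    return False


def match_flags(
    avars: Sequence[NormalizedVariant],
    bvars: Sequence[NormalizedVariant],
    mode: str = EXACT,
) -> tuple[list[bool], list[bool]]:
    """Vectorised matching of two call sets.

    Returns (matched_a, matched_b): for each variant, whether some variant of
    the other set matches it under ``mode``.  Equivalent to all-pairs
    :func:`match` but near-linear for large sets.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    akeys = {v.key for v in avars}
    bkeys = {v.key for v in bvars}
    matched_a = [v.key in bkeys for v in avars]
    matched_b = [v.key in akeys for v in bvars]
    if mode == OVERLAP_INDEL:
        a_spans = _indel_span_index(avars)
        b_spans = _indel_span_index(bvars)
        for flags, vars_, other in ((matched_a, avars, b_spans),
                                    (matched_b, bvars, a_spans)):
            for i, v in enumerate(vars_):
                if not flags[i] and v.vtype == INDEL:
                    flags[i] = _span_hit(other, v.span)
    return matched_a, matched_b


def _indel_span_index(vars_) -> dict[str, tuple[list[int], list[int]]]:
    """chrom -> (sorted starts, running-max ends) over INDEL spans."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for v in vars_:
        if v.vtype == INDEL:
            s = v.span
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    index = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = [s for s, _ in spans]
        ends: list[int] = []
        mx = 0
        for _, e in spans:
            mx = max(mx, e)
            ends.append(mx)
        index[chrom] = (starts, ends)
    return index


def _span_hit(index, span: GenomicInterval) -> bool:
    idx = index.get(span.chrom)
    if idx is None:
        return False
    starts, maxends = idx
    i = bisect_right(starts, span.end - 1)  # spans starting before span.end
    return i > 0 and maxends[i - 1] > span.start


def in_regions(v: NormalizedVariant, regions: TargetRegions) -> bool:
    """True iff the variant's reference span intersects any target interval.

    Partial overlap counts: an INDEL whose breakpoint lies outside the BED
    interval but whose span touches it is inside.
    """
    s = v.span
    return regions.overlaps(s.chrom, s.start, s.end)
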