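"""Per-transcript consequence annotations (VEP-CSQ dialect).

Parses the comma/pipe-delimited consequence INFO field, restricts variants to
canonical transcripts (one counting unit per (variant, gene) pair — a variant
canonical in k genes contributes k units downstream), classifies the genomic
region of a consequence-term list, and applies the clinical-relevance rule:
ClinVar significance restricted to pathogenic / likely pathogenic / uncertain
significance, with VUS-only variants additionally required to have gnomAD
POPMAX AF below 0.1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .variantcore import NormalizedVariant, VariantKey

log = logging.getLogger(__name__)

REGION_CLASSES = ("exonic", "splicing", "utr5", "utr3", "ncRNA", "intronic",
                  "upstream", "downstream", "intergenic", "other")
# precedence for multi-consequence variants: earlier wins
_PRECEDENCE = {c: i for i, c in enumerate(REGION_CLASSES)}

RELEVANT_CLINVAR = frozenset(
    {"pathogenic", "likely_pathogenic", "uncertain_significance"})


class AnnotationFormatError(ValueError):
    """CSQ block does not match the declared field format."""


def _load_region_map() -> dict[str, str]:
    text = (resources.files("reanalyzer.data") / "so_region_map.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, cls = line.split("\t")
        if cls not in REGION_CLASSES:
            raise ValueError(f"unknown region class {cls!r} in region map")
        table[term] = cls
    return table


SO_REGION_MAP = _load_region_map()

_warned_terms: set[str] = set()


def classify_region(consequence_terms: Sequence[str]) -> str:
    """Highest-precedence region class matched by any consequence term.

    Precedence: exonic > splicing > utr5 > utr3 > ncRNA > intronic >
    upstream > downstream > intergenic > other.  Unknown terms map to
    ``other`` with a one-time logged warning.
    """
    best = "other"
    for term in consequence_terms:
        cls = SO_REGION_MAP.get(term)
        if cls is None:
            if term not in _warned_terms:
                log.warning("unknown consequence term %r -> 'other'", term)
                _warned_terms.add(term)
            cls = "other"
        if _PRECEDENCE[cls] < _PRECEDENCE[best]:
            best = cls
    return best


_CLINVAR_SPLIT = re.compile(r"[&/|,]+")


def parse_clinvar_labels(raw: str) -> frozenset[str]:
    """Split a ClinVar significance string into a lower-cased label set.

    Handles the "/", ",", "|", "&" and "Pathogenic/Likely_pathogenic"
    dialects; review-status qualifiers are kept as-is (they simply fail the
    relevance whitelist).  Empty input gives the empty set.
    """
    labels = set()
    for tok in _CLINVAR_SPLIT.split(raw.strip()):
        tok = tok.strip().lower().replace(" ", "_").strip("_")
        if tok:
            labels.add(tok)
    return frozenset(labels)


@dataclass(eq=True)
class TranscriptAnnotation:
    """One per-transcript consequence record from the annotation INFO field."""

    variant_key: Optional[VariantKey] = None
    allele: Optional[str] = None
    gene_symbol: Optional[str] = None
    transcript_id: Optional[str] = None
    canonical: bool = False
    consequence_terms: tuple[str, ...] = ()
    hgvs_c: Optional[str] = None
    clinvar_sig: frozenset[str] = frozenset()
    af_gnomad: Optional[float] = None
    af_popmax: Optional[float] = None
    af_max: Optional[float] = None
    af_exac: Optional[float] = None
    af_1000g: Optional[float] = None
    cadd: Optional[float] = None
    sift: Optional[str] = None
    polyphen: Optional[str] = None
    maxentscan: Optional[str] = None

    @property
    def region_class(self) -> str:
        return classify_region(self.consequence_terms)

    def source_afs(self) -> list[float]:
        """The per-source allele frequencies that are present."""
        return [a for a in (self.af_exac, self.af_1000g, self.af_gnomad)
                if a is not None]

    def max_af(self) -> Optional[float]:
        """Maximum AF: the dedicated field when present, else the max over
        the available ExAC/1000G/gnomAD fields."""
        if self.af_max is not None:
            return self.af_max
        afs = self.source_afs()
        return max(afs) if afs else None


@dataclass
class AnnotatedVariant:
    """A normalized variant together with its per-transcript annotations."""

    variant: NormalizedVariant
    annotations: list[TranscriptAnnotation] = field(default_factory=list)

    def canonical_annotations(self) -> list[TranscriptAnnotation]:
        return select_canonical(self)


# field-name aliases accepted in the CSQ format line (VEP dialects vary)
_FIELD_ALIASES = {
    "allele": "allele",
    "consequence": "consequence",
    "symbol": "gene_symbol",
    "gene_symbol": "gene_symbol",
    "feature": "transcript_id",
    "transcript_id": "transcript_id",
    "canonical": "canonical",
    "hgvsc": "hgvs_c",
    "clin_sig": "clinvar_sig",
    "clinvar_clnsig": "clinvar_sig",
    "gnomadg_af": "af_gnomad",
    "gnomad_af": "af_gnomad",
    "gnomadg_af_popmax": "af_popmax",
    "gnomad_af_popmax": "af_popmax",
    "max_af": "af_max",
    "exac_af": "af_exac",
    "af_1000g": "af_1000g",
    "1000g_af": "af_1000g",
    "af": "af_1000g",  # bare VEP "AF" is the 1000G phase-3 frequency
    "cadd_phred": "cadd",
    "sift": "sift",
    "polyphen": "polyphen",
    "maxentscan_diff": "maxentscan",
}

_FLOAT_FIELDS = {"af_gnomad", "af_popmax", "af_max", "af_exac", "af_1000g", "cadd"}


def parse_csq(
    vcf_info_field: str,
    csq_format: Sequence[str],
    variant_key: Optional[VariantKey] = None,
) -> list[TranscriptAnnotation]:
    """Parse a VEP-style consequence INFO value into annotation records.

    ``csq_format`` is the ordered field-name list from the VCF header
    description of the annotation key.  Empty sub-fields become absent
    values; AF sub-fields are parsed to floats.  Raises
    :class:`AnnotationFormatError` when a block's pipe count does not match
    the format.
    """
    if not vcf_info_field:
        return []
    slots = [_FIELD_ALIASES.get(name.lower()) for name in csq_format]
    out = []
    for block in vcf_info_field.split(","):
        parts = block.split("|")
        if len(parts) != len(slots):
            raise AnnotationFormatError(
                f"CSQ block has {len(parts)} fields, format declares "
                f"{len(slots)}: {block[:80]!r}")
        ann = TranscriptAnnotation(variant_key=variant_key)
        for value, slot in zip(parts, slots):
            if slot is None or value == "":
                continue
            if slot == "consequence":
                ann.consequence_terms = tuple(value.split("&"))
            elif slot == "canonical":
                ann.canonical = value.upper() in ("YES", "1", "TRUE")
            elif slot == "clinvar_sig":
                ann.clinvar_sig = parse_clinvar_labels(value)
            elif slot in _FLOAT_FIELDS:
                try:
                    x = float(value)
                except ValueError as exc:
                    raise AnnotationFormatError(
                        f"non-numeric {slot} value {value!r}") from exc
                if slot != "cadd" and not 0.0 <= x <= 1.0:
                    raise AnnotationFormatError(
                        f"allele frequency out of [0,1]: {slot}={value}")
                setattr(ann, slot, x)
            else:
                setattr(ann, slot, value)
        out.append(ann)
    return out


def format_csq(
    annotations: Iterable[TranscriptAnnotation],
    csq_format: Sequence[str],
) -> str:
    """Serialize annotations back to the CSQ wire format (parse round-trip)."""
    slots = [_FIELD_ALIASES.get(name.lower()) for name in csq_format]
    blocks = []
    for ann in annotations:
        parts = []
        for slot in slots:
            if slot is None:
                parts.append("")
            elif slot == "consequence":
                parts.append("&".join(ann.consequence_terms))
            elif slot == "canonical":
                parts.append("YES" if ann.canonical else "")
            elif slot == "clinvar_sig":
                parts.append("&".join(sorted(ann.clinvar_sig)))
            else:
                v = getattr(ann, slot)
                if v is None:
                    parts.append("")
                elif isinstance(v, float):
                    parts.append(repr(float(v)))
                else:
                    parts.append(str(v))
        blocks.append("|".join(parts))
    return ",".join(blocks)


def select_canonical(av: AnnotatedVariant) -> list[TranscriptAnnotation]:
    """Canonical-transcript annotations, one per (variant, gene) pair.

    A variant in canonical transcripts of k distinct genes contributes k
    counting units downstream.  Two canonical transcripts of the same gene
    are tie-broken on the lexicographically smallest transcript id.
    """
    by_gene: dict[str, TranscriptAnnotation] = {}
    for ann in av.annotations:
        if not ann.canonical:
            continue
        gene = ann.gene_symbol or ""
        cur = by_gene.get(gene)
        if cur is None or (ann.transcript_id or "") < (cur.transcript_id or ""):
            by_gene[gene] = ann
    return [by_gene[g] for g in sorted(by_gene)]


def is_clinically_relevant(
    t: TranscriptAnnotation, popmax_cutoff: float = 0.1
) -> bool:
    """The clinical-relevance rule.

    True iff the ClinVar label set is non-empty and contains only
    pathogenic / likely pathogenic / uncertain significance labels; when the
    variant is VUS-only, its gnomAD POPMAX AF must additionally be below
    ``popmax_cutoff`` (an absent POPMAX passes: absent from gnomAD implies
    rare).
    """
    sig = t.clinvar_sig
    if not sig or not sig <= RELEVANT_CLINVAR:
        return False
    if sig == {"uncertain_significance"}:
        if t.af_popmax is not None and t.af_popmax >= popmax_cutoff:
            return False
    return True
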