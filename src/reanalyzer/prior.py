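"""The reanalysis engine: staged variant filtering and prioritization.

For unsolved cases, variants from the reanalysis pipeline (canonical
transcripts, already restricted to Maximum AF < 0.05) are funnelled through:

(0) a Maximum-AF prefilter (< 0.05, toggleable — the upstream pipeline may
    already have applied it);
(i) allele-frequency rarity: every available per-source AF (ExAC, 1000G,
    gnomAD) < 0.01 AND gnomAD POPMAX AF < 0.01, absent values passing;
(ii) the differential filter: variants matching a call in the same sample's
    commercial VCF are removed (overlap matching by default so
    representation-shifted INDELs are not falsely retained);
(iii) a virtual gene panel: keep variants whose gene symbol is on the panel.

Survivors are deterministically prioritized: tier 1 = INDELs (any region),
tier 2 = non-exonic SNVs, tier 3 = exonic SNVs; within a tier by ClinVar
significance (pathogenic < likely pathogenic < VUS < none), CADD descending
(absent last), then genomic coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import AnnotatedVariant, TranscriptAnnotation, select_canonical
from .variantcore import (INDEL, OVERLAP_INDEL, NormalizedVariant,
                          match_flags)

log = logging.getLogger(__name__)

STAGE_LABELS = ("input", "prefilter_maxaf", "af_popmax", "differential", "panel")


class PanelError(ValueError):
    """Panel filtering requested with an empty panel."""


@dataclass
class CascadeConfig:
    max_af_prefilter: float = 0.05
    af_cutoff: float = 0.01
    popmax_cutoff: float = 0.01
    prefilter_enabled: bool = True
    differential_filter: bool = True
    panel_genes: Optional[frozenset[str]] = None
    match_mode: str = OVERLAP_INDEL

    def __post_init__(self) -> None:
        for name in ("max_af_prefilter", "af_cutoff", "popmax_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.panel_genes is not None:
            self.panel_genes = frozenset(g.upper() for g in self.panel_genes)


@dataclass(frozen=True)
class PrioritizedVariant:
    annotated: AnnotatedVariant
    tier: int  # 1 = INDEL, 2 = non-exonic SNV, 3 = exonic SNV
    clinvar_rank: int  # 0 pathogenic, 1 likely pathogenic, 2 VUS, 3 none
    cadd: Optional[float]


@dataclass
class CascadeReport:
    stages: list[tuple[str, int]]  # (label, surviving count), non-increasing
    survivors: list[PrioritizedVariant]
    config: CascadeConfig

    def stage_counts(self) -> dict[str, int]:
        return dict(self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": [{"label": l, "count": c} for l, c in self.stages],
            "n_survivors": len(self.survivors),
        }


def _primary_annotation(av: AnnotatedVariant) -> Optional[TranscriptAnnotation]:
    anns = select_canonical(av) or av.annotations
    return anns[0] if anns else None


def _passes_af_stage(av: AnnotatedVariant, cfg: CascadeConfig) -> bool:
    ann = _primary_annotation(av)
    if ann is None:
        return True  # unannotated variants are treated as rare
    if any(a >= cfg.af_cutoff for a in ann.source_afs()):
        return False
    return ann.af_popmax is None or ann.af_popmax < cfg.popmax_cutoff


def _passes_prefilter(av: AnnotatedVariant, cfg: CascadeConfig) -> bool:
    ann = _primary_annotation(av)
    if ann is None:
        return True
    mx = ann.max_af()
    return mx is None or mx < cfg.max_af_prefilter


def _genes(av: AnnotatedVariant) -> set[str]:
    return {ann.gene_symbol.upper()
            for ann in (select_canonical(av) or av.annotations)
            if ann.gene_symbol}


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    commercial: Mapping[str, Sequence[NormalizedVariant]],
    cfg: Optional[CascadeConfig] = None,
) -> CascadeReport:
    """Run the staged filtering cascade and prioritize the survivors.

    ``variants`` are the reanalysis pipeline's annotated calls (their
    ``sample_id`` selects the commercial call set used by the differential
    stage).  Stage order: prefilter (Maximum AF), AF/POPMAX rarity,
    differential, panel; each stage's survivor set is a subset of the
    previous one and the per-stage counts are recorded.
    """
    cfg = cfg or CascadeConfig()
    stages: list[tuple[str, int]] = [("input", len(variants))]
    surv = list(variants)

    if cfg.prefilter_enabled:
        surv = [av for av in surv if _passes_prefilter(av, cfg)]
    stages.append(("prefilter_maxaf", len(surv)))

    surv = [av for av in surv if _passes_af_stage(av, cfg)]
    stages.append(("af_popmax", len(surv)))

    if cfg.differential_filter:
        by_sample: dict[str, list[AnnotatedVariant]] = {}
        for av in surv:
            by_sample.setdefault(av.variant.sample_id or "", []).append(av)
        kept: list[AnnotatedVariant] = []
        for sid, avs in by_sample.items():
            comm = list(commercial.get(sid, ()))
            flags, _ = match_flags([av.variant for av in avs], comm,
                                   cfg.match_mode)
            kept.extend(av for av, hit in zip(avs, flags) if not hit)
        order = {id(av): i for i, av in enumerate(surv)}
        surv = sorted(kept, key=lambda av: order[id(av)])
    stages.append(("differential", len(surv)))

    if cfg.panel_genes is not None:
        if not cfg.panel_genes:
            raise PanelError("panel stage enabled with an empty panel")
        surv = [av for av in surv if _genes(av) & cfg.panel_genes]
    stages.append(("panel", len(surv)))

    for (_, a), (_, b) in zip(stages, stages[1:]):
        assert b <= a, "cascade stages must be non-increasing"
    return CascadeReport(stages=stages, survivors=prioritize(surv), config=cfg)


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------

def _clinvar_rank(av: AnnotatedVariant) -> int:
    best = 3
    for ann in (select_canonical(av) or av.annotations):
        sig = ann.clinvar_sig
        if "pathogenic" in sig:
            best = min(best, 0)
        elif "likely_pathogenic" in sig:
            best = min(best, 1)
        elif "uncertain_significance" in sig:
            best = min(best, 2)
    return best


def _best_region(av: AnnotatedVariant) -> str:
    from .annotation import REGION_CLASSES
    regions = [ann.region_class for ann in (select_canonical(av) or av.annotations)]
    if not regions:
        return "other"
    order = {c: i for i, c in enumerate(REGION_CLASSES)}
    return min(regions, key=lambda r: order[r])


def _cadd(av: AnnotatedVariant) -> Optional[float]:
    vals = [ann.cadd for ann in av.annotations if ann.cadd is not None]
    return max(vals) if vals else None


def assign_tier(av: AnnotatedVariant) -> int:
    """1 = INDEL (any region), 2 = non-exonic SNV, 3 = exonic SNV."""
    if av.variant.vtype == INDEL:
        return 1
    return 2 if _best_region(av) != "exonic" else 3


def prioritize(survivors: Sequence[AnnotatedVariant]) -> list[PrioritizedVariant]:
    """Total, deterministic ordering of cascade survivors."""
    pvs = [PrioritizedVariant(av, assign_tier(av), _clinvar_rank(av), _cadd(av))
           for av in survivors]
    return sorted(pvs, key=lambda p: (
        p.tier, p.clinvar_rank,
        p.cadd is None, -(p.cadd or 0.0),
        p.annotated.variant.chrom, p.annotated.variant.pos,
        p.annotated.variant.ref, p.annotated.variant.alt,
        p.annotated.variant.sample_id or "",
    ))


# ---------------------------------------------------------------------------
# Analyst export
# ---------------------------------------------------------------------------

EXPORT_COLUMNS = (
    "sample", "chrom", "pos", "ref", "alt", "vtype", "tier", "gene",
    "region_class", "clinvar", "cadd", "af_gnomad", "af_popmax", "af_max",
    "hgvs_c", "transcript", "qual", "dp", "vaf",
)


def review_export(report: CascadeReport,
                  sample_meta: Optional[Mapping[str, Mapping]] = None,
                  ) -> pd.DataFrame:
    """One row per survivor, in prioritize order, with deterministic columns.

    ``sample_meta`` (sample id -> extra fields) is joined in when given; the
    table round-trips losslessly through TSV.
    """
    rows = []
    for pv in report.survivors:
        v = pv.annotated.variant
        ann = _primary_annotation(pv.annotated)
        row = {
            "sample": v.sample_id,
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "vtype": v.vtype, "tier": pv.tier,
            "gene": ann.gene_symbol if ann else None,
            "region_class": ann.region_class if ann else None,
            "clinvar": "&".join(sorted(ann.clinvar_sig)) if ann else "",
            "cadd": pv.cadd,
            "af_gnomad": ann.af_gnomad if ann else None,
            "af_popmax": ann.af_popmax if ann else None,
            "af_max": ann.max_af() if ann else None,
            "hgvs_c": ann.hgvs_c if ann else None,
            "transcript": ann.transcript_id if ann else None,
            "qual": v.qual,
            "dp": v.info.get("DP"),
            "vaf": v.vaf,
        }
        if sample_meta and v.sample_id in sample_meta:
            row.update(sample_meta[v.sample_id])
        rows.append(row)
    base = list(EXPORT_COLUMNS)
    extra = sorted({k for r in rows for k in r} - set(base))
    return pd.DataFrame(rows, columns=base + extra)


def read_panel(path) -> frozenset[str]:
    """Newline-delimited gene symbols; '#' comments and blanks ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line.upper())
    return frozenset(genes)
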