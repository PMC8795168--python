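"""Deterministic generator of paired-pipeline synthetic cohorts.

Emulates the statistical structure that the downstream comparisons assume:
two variant-calling pipelines (A = "commercial", B = "in-house") sharing most
calls, with B additionally reporting variants that lie only in the +/-1000 bp
padding of the targeted regions; an allele-frequency spectrum in which
pipeline-unique calls are rarer than shared ones (so that a ~4000-variant
sample funnels through the reanalysis cascade to roughly 1000 / 300 / 45
survivors); ClinVar label planting; per-predicate QC-failure injection; and
planted causal-variant scenarios (a splice SNV detectable only with padding,
a second-allele exonic INDEL in a panel gene, a causal SNV at 18% VAF).

Every emitted variant is recorded in a truth table carrying its construction
provenance and expected downstream fate, which the rest of the package is
tested against.  All output is byte-deterministic under the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (AnnotatedVariant, TranscriptAnnotation,
                         parse_clinvar_labels)
from .causal import CausalRecord, write_causal_table
from .variantcore import (DictReference, GenomicInterval, INDEL,
                          NormalizedVariant, RawVariantRecord, SNV,
                          TargetRegions, VariantKey, normalize)

log = logging.getLogger(__name__)

CSQ_FIELDS = ["Allele", "Consequence", "SYMBOL", "Feature", "CANONICAL",
              "HGVSc", "CLIN_SIG", "gnomADg_AF", "gnomADg_AF_POPMAX",
              "MAX_AF", "ExAC_AF", "AF_1000G", "CADD_PHRED"]

REGION_TERMS = {
    ("exonic", SNV): ("missense_variant",),
    ("exonic", INDEL): ("frameshift_variant",),
    ("splicing", SNV): ("splice_acceptor_variant", "intron_variant"),
    ("splicing", INDEL): ("splice_acceptor_variant", "intron_variant"),
    ("utr5", SNV): ("5_prime_UTR_variant",),
    ("utr5", INDEL): ("5_prime_UTR_variant",),
    ("utr3", SNV): ("3_prime_UTR_variant",),
    ("utr3", INDEL): ("3_prime_UTR_variant",),
    ("intronic", SNV): ("intron_variant",),
    ("intronic", INDEL): ("intron_variant",),
    ("upstream", SNV): ("upstream_gene_variant",),
    ("upstream", INDEL): ("upstream_gene_variant",),
    ("downstream", SNV): ("downstream_gene_variant",),
    ("downstream", INDEL): ("downstream_gene_variant",),
    ("ncRNA", SNV): ("non_coding_transcript_exon_variant",),
    ("ncRNA", INDEL): ("non_coding_transcript_exon_variant",),
}

ASSIGN_BOTH = "both"
ASSIGN_A = "a_only"
ASSIGN_B = "b_only"
ASSIGN_PADDING = "padding_only"

_QC_SNV_CODES = ("SNP_QD", "SNP_MQ", "SNP_MQRankSum", "SNP_ReadPosRankSum",
                 "NOT_PASS_FLAG", "LOW_DP", "LOW_QUAL")
_QC_INDEL_CODES = ("INDEL_QD", "INDEL_ReadPosRankSum",
                   "NOT_PASS_FLAG", "LOW_DP", "LOW_QUAL")
_HARD_CODES = {"SNP_QD", "SNP_MQ", "SNP_MQRankSum", "SNP_ReadPosRankSum",
               "INDEL_QD", "INDEL_ReadPosRankSum"}
_QUALITY_CODES = {"NOT_PASS_FLAG", "LOW_DP", "LOW_QUAL"}

DEFAULT_CAUSAL_PLAN = (
    ("found", 3),
    ("padding_splice_snv", 1),
    ("second_allele_exonic_indel", 1),
    ("low_vaf_snv", 1),
    ("hard_filter_fail", 1),
    ("absent_from_calls", 1),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the structure of the targeted-resequencing comparison:
    100 samples of ~4000 variants each, 88% of calls shared between the two
    pipelines, B-only calls enriched in the rare allele-frequency component
    so the cascade funnels a sample to roughly 1000 / 300 / 45 survivors.
    """

    seed: int = 7
    n_samples: int = 100
    variants_per_sample: int = 4000
    # target geometry
    n_genes: int = 60
    targets_per_gene: int = 6
    target_len: int = 250
    target_gap: int = 2600   # within-gene distance between targets
    gene_gap: int = 6000     # distance between the last/first targets of genes
    pad_bp: int = 1000
    # variant composition
    fraction_indel: float = 0.12
    indel_max_len: int = 6
    region_mix: dict = field(default_factory=lambda: {
        "exonic": 0.34, "intronic": 0.30, "utr5": 0.05, "utr3": 0.07,
        "splicing": 0.05, "upstream": 0.08, "downstream": 0.08, "ncRNA": 0.03})
    padding_region_mix: dict = field(default_factory=lambda: {
        "splicing": 0.5, "intronic": 0.5})
    # pipeline assignment
    p_both: float = 0.88
    p_only_a: float = 0.03
    p_only_b: float = 0.04
    padding_only_rate: float = 0.05
    # allele-frequency model (all frequencies < 0.05: upstream Maximum-AF
    # prefilter applied); unique calls draw the rare component more often
    p_af_absent: float = 0.05
    p_rare_shared: float = 0.16
    p_rare_unique: float = 0.75
    rare_af_range: tuple = (1e-6, 0.01)
    low_af_range: tuple = (0.01, 0.05)
    # ClinVar planting
    clinvar_rates: dict = field(default_factory=lambda: {
        "pathogenic": 0.01, "likely_pathogenic": 0.01,
        "uncertain_significance": 0.04, "benign": 0.03})
    # QC-failure injection (total probability; code drawn uniformly among
    # the codes applicable to the variant type)
    qc_failure_rate: float = 0.015
    hom_rate: float = 0.05
    multi_gene_rate: float = 0.02
    panel_fraction: float = 0.15
    causal_plan: tuple = DEFAULT_CAUSAL_PLAN

    def __post_init__(self) -> None:
        p = (self.p_both, self.p_only_a, self.p_only_b, self.padding_only_rate)
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("pipeline assignment probabilities must sum to 1")
        for mix in (self.region_mix, self.padding_region_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("region mix must sum to 1")
        if not all(0 <= v <= 1 for v in
                   list(self.clinvar_rates.values())
                   + [self.fraction_indel, self.qc_failure_rate,
                      self.p_af_absent, self.p_rare_shared,
                      self.p_rare_unique, self.hom_rate,
                      self.multi_gene_rate, self.panel_fraction]):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class Gene:
    name: str
    transcript_id: str
    intervals: list[GenomicInterval]
    in_panel: bool = False


@dataclass
class Cohort:
    config: SimConfig
    reference: DictReference
    contig_lengths: dict[str, int]
    targets: TargetRegions
    genes: list[Gene]
    panel: frozenset[str]
    annotated_a: dict[str, list[AnnotatedVariant]]
    annotated_b: dict[str, list[AnnotatedVariant]]
    truth: pd.DataFrame
    causal_records: list[CausalRecord] = field(default_factory=list)
    csq_fields: list[str] = field(default_factory=lambda: list(CSQ_FIELDS))

    @property
    def padded_targets(self) -> TargetRegions:
        return self.targets.pad(self.config.pad_bp)

    def calls_a(self) -> dict[str, list[NormalizedVariant]]:
        return {s: [av.variant for av in avs]
                for s, avs in self.annotated_a.items()}

    def calls_b(self) -> dict[str, list[NormalizedVariant]]:
        return {s: [av.variant for av in avs]
                for s, avs in self.annotated_b.items()}

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.annotated_b)


# ---------------------------------------------------------------------------
# Targets and reference
# ---------------------------------------------------------------------------

def gen_targets(cfg: SimConfig,
                rng: Optional[np.random.Generator] = None,
                ) -> tuple[TargetRegions, list[Gene], dict[str, int]]:
    """Deterministic non-overlapping target intervals grouped into genes."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    margin = 2 * cfg.pad_bp
    genes: list[Gene] = []
    ivs: list[GenomicInterval] = []
    pos = margin
    chrom = "1"
    panel_idx = _panel_gene_indices(cfg)
    for g in range(cfg.n_genes):
        g_ivs = []
        for _ in range(cfg.targets_per_gene):
            iv = GenomicInterval(chrom, pos, pos + cfg.target_len)
            g_ivs.append(iv)
            ivs.append(iv)
            pos += cfg.target_len + cfg.target_gap
        pos += cfg.gene_gap - cfg.target_gap
        genes.append(Gene(
            name=f"GENE{g:03d}", transcript_id=f"NM_{100000 + g}.1",
            intervals=g_ivs, in_panel=g in panel_idx))
    contig_len = pos + margin
    if contig_len > 50_000_000:
        raise ValueError("interval budget infeasible for contig length")
    return TargetRegions(ivs), genes, {chrom: contig_len}


def _panel_gene_indices(cfg: SimConfig) -> set[int]:
    n = max(1, round(cfg.panel_fraction * cfg.n_genes))
    # evenly spread, deterministic in the config alone
    return {round(i * cfg.n_genes / n) % cfg.n_genes for i in range(n)}


def _gen_reference(rng: np.random.Generator,
                   contig_lengths: dict[str, int]) -> DictReference:
    seqs = {}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in contig_lengths.items():
        idx = rng.integers(0, 4, size=length)
        seqs[chrom] = lut[idx].tobytes().decode("ascii")
    return DictReference(seqs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def gen_cohort(cfg: SimConfig) -> Cohort:
    """Generate the paired-pipeline cohort with its truth table."""
    rng = np.random.default_rng(cfg.seed)
    targets, genes, contig_lengths = gen_targets(cfg, rng)
    reference = _gen_reference(rng, contig_lengths)
    panel = frozenset(g.name for g in genes if g.in_panel)

    region_names = list(cfg.region_mix)
    region_probs = np.array([cfg.region_mix[r] for r in region_names])
    pad_names = list(cfg.padding_region_mix)
    pad_probs = np.array([cfg.padding_region_mix[r] for r in pad_names])
    assign_names = (ASSIGN_BOTH, ASSIGN_A, ASSIGN_B, ASSIGN_PADDING)
    assign_probs = np.array([cfg.p_both, cfg.p_only_a, cfg.p_only_b,
                             cfg.padding_only_rate])
    assign_probs = assign_probs / assign_probs.sum()
    region_probs = region_probs / region_probs.sum()
    pad_probs = pad_probs / pad_probs.sum()
    cv_probs = np.array(list(cfg.clinvar_rates.values())
                        + [1.0 - sum(cfg.clinvar_rates.values())])
    cv_names = list(cfg.clinvar_rates) + [""]
    cv_probs = cv_probs / cv_probs.sum()

    annotated_a: dict[str, list[AnnotatedVariant]] = {}
    annotated_b: dict[str, list[AnnotatedVariant]] = {}
    truth_rows: list[dict] = []

    for s in range(cfg.n_samples):
        sid = f"S{s:04d}"
        n = cfg.variants_per_sample
        assign = rng.choice(len(assign_names), size=n, p=assign_probs)
        region_i = rng.choice(len(region_names), size=n, p=region_probs)
        pad_region_i = rng.choice(len(pad_names), size=n, p=pad_probs)
        is_indel = rng.random(n) < cfg.fraction_indel
        indel_is_del = rng.random(n) < 0.5
        indel_len = rng.integers(1, cfg.indel_max_len + 1, size=n)
        gene_i = rng.integers(0, cfg.n_genes, size=n)
        tgt_i = rng.integers(0, cfg.targets_per_gene, size=n)
        offset = rng.integers(0, cfg.target_len, size=n)
        pad_side = rng.integers(0, 2, size=n)
        pad_dist = rng.integers(8, cfg.pad_bp - 50, size=n)
        af_u = rng.random(n)
        af_val = rng.random(n)
        popmax_mult = rng.uniform(1.0, 3.0, size=n)
        af_jit = rng.uniform(0.8, 1.2, size=(n, 2))
        cv_i = rng.choice(len(cv_names), size=n, p=cv_probs)
        qc_u = rng.random(n)
        qc_pick = rng.random(n)
        dp = rng.integers(50, 201, size=n)
        qual = rng.uniform(150.0, 3000.0, size=n)
        hom = rng.random(n) < cfg.hom_rate
        het_vaf = np.clip(rng.normal(0.5, 0.05, size=n), 0.25, 0.75)
        hom_vaf = np.clip(rng.normal(0.98, 0.01, size=n), 0.9, 1.0)
        qd = rng.uniform(5.0, 30.0, size=n)
        mq = rng.uniform(50.0, 60.0, size=n)
        mqrs = rng.normal(0.0, 1.0, size=n)
        rprs = rng.normal(0.0, 1.0, size=n)
        cadd_present = rng.random(n) < 0.8
        cadd_val = rng.uniform(0.0, 40.0, size=n)
        multi_gene = rng.random(n) < cfg.multi_gene_rate
        alt_pick = rng.integers(0, 3, size=n)
        ins_seq_i = rng.integers(0, 4, size=(n, cfg.indel_max_len))

        a_list: list[AnnotatedVariant] = []
        b_list: list[AnnotatedVariant] = []
        seen_keys: set[VariantKey] = set()
        indel_occupied: set[int] = set()

        for i in range(n):
            asg = assign_names[assign[i]]
            in_padding = asg == ASSIGN_PADDING
            region = (pad_names[pad_region_i[i]] if in_padding
                      else region_names[region_i[i]])
            gene = genes[gene_i[i]]
            tgt = gene.intervals[tgt_i[i]]
            if in_padding:
                if pad_side[i] == 0:
                    p0 = tgt.start - int(pad_dist[i])
                else:
                    p0 = tgt.end - 1 + int(pad_dist[i])
            else:
                p0 = tgt.start + int(offset[i])

            vt = INDEL if is_indel[i] else SNV
            nv = _build_variant(
                reference, "1", p0, vt, bool(indel_is_del[i]),
                int(indel_len[i]), int(alt_pick[i]), ins_seq_i[i])
            if nv is None:
                continue
            # enforce construction invariants after left-alignment
            span = nv.span
            if in_padding:
                if targets.overlaps(span.chrom, span.start, span.end):
                    continue
            else:
                if not targets.overlaps(span.chrom, span.start, span.end):
                    continue
            if nv.key in seen_keys:
                continue
            if nv.vtype == INDEL:
                cells = range(span.start, span.end)
                if any(c in indel_occupied for c in cells):
                    continue
                indel_occupied.update(cells)
            seen_keys.add(nv.key)

            # call-quality layer
            qc_code = ""
            if qc_u[i] < cfg.qc_failure_rate:
                codes = _QC_INDEL_CODES if vt == INDEL else _QC_SNV_CODES
                qc_code = codes[int(qc_pick[i] * len(codes))]
            vaf = float(hom_vaf[i] if hom[i] else het_vaf[i])
            metrics = {"QD": round(float(qd[i]), 2),
                       "MQ": round(float(mq[i]), 2),
                       "MQRankSum": round(float(mqrs[i]), 3),
                       "ReadPosRankSum": round(float(rprs[i]), 3),
                       "DP": int(dp[i])}
            q = round(float(qual[i]), 2)
            filt = "PASS"
            if qc_code == "SNP_QD" or qc_code == "INDEL_QD":
                metrics["QD"] = 1.0
            elif qc_code == "SNP_MQ":
                metrics["MQ"] = 30.0
            elif qc_code == "SNP_MQRankSum":
                metrics["MQRankSum"] = -13.0
            elif qc_code == "SNP_ReadPosRankSum":
                metrics["ReadPosRankSum"] = -9.0
            elif qc_code == "INDEL_ReadPosRankSum":
                metrics["ReadPosRankSum"] = -21.0
            elif qc_code == "NOT_PASS_FLAG":
                filt = "INDEL_filter" if vt == INDEL else "SNP_filter"
            elif qc_code == "LOW_DP":
                metrics["DP"] = 8
            elif qc_code == "LOW_QUAL":
                q = 50.0
            nv.qual = q
            nv.filter = filt
            nv.info = metrics
            nv.vaf = vaf
            nv.sample_id = sid

            # allele frequencies
            unique = asg in (ASSIGN_B, ASSIGN_PADDING, ASSIGN_A)
            p_rare = cfg.p_rare_unique if unique else cfg.p_rare_shared
            afs = _draw_afs(cfg, float(af_u[i]), float(af_val[i]),
                            float(popmax_mult[i]), af_jit[i], p_rare)
            af_gnomad, af_popmax, af_exac, af_1000g, af_max = afs

            clinvar = cv_names[cv_i[i]]
            cadd = round(float(cadd_val[i]), 1) if cadd_present[i] else None
            anns = [_make_annotation(
                nv, gene, region, vt, clinvar, af_gnomad, af_popmax,
                af_exac, af_1000g, af_max, cadd)]
            second_class = ""
            if multi_gene[i]:
                g2 = genes[(gene_i[i] + 1) % cfg.n_genes]
                second_class = "upstream"
                anns.append(_make_annotation(
                    nv, g2, second_class, vt, clinvar, af_gnomad, af_popmax,
                    af_exac, af_1000g, af_max, cadd))
            av = AnnotatedVariant(variant=nv, annotations=anns)

            if asg in (ASSIGN_BOTH, ASSIGN_A):
                a_list.append(av)
            if asg in (ASSIGN_BOTH, ASSIGN_B, ASSIGN_PADDING):
                b_list.append(av)

            truth_rows.append(_truth_row(
                cfg, sid, nv, asg, region, second_class, gene, panel,
                clinvar, qc_code, af_gnomad, af_popmax, af_exac, af_1000g,
                af_max, anns))
        annotated_a[sid] = a_list
        annotated_b[sid] = b_list

    truth = pd.DataFrame(truth_rows)
    return Cohort(
        config=cfg, reference=reference, contig_lengths=contig_lengths,
        targets=targets, genes=genes, panel=panel,
        annotated_a=annotated_a, annotated_b=annotated_b, truth=truth)


def _build_variant(reference, chrom, p0, vt, is_del, ilen, alt_pick,
                   ins_seq_idx) -> Optional[NormalizedVariant]:
    """Construct and left-align one variant anchored at 0-based p0."""
    bases = "ACGT"
    try:
        anchor = reference.fetch(chrom, p0, p0 + 1)
    except KeyError:
        return None
    if not anchor:
        return None
    if vt == SNV:
        alts = [b for b in bases if b != anchor]
        ref, alt = anchor, alts[alt_pick % 3]
        nv = NormalizedVariant(chrom=chrom, pos=p0 + 1, ref=ref, alt=alt,
                               vtype=SNV, qual=None, filter="PASS", info={},
                               vaf=None, sample_id=None, mnv=False)
        return nv
    if is_del:
        ref = reference.fetch(chrom, p0, p0 + 1 + ilen)
        if len(ref) != 1 + ilen:
            return None
        alt = ref[0]
    else:
        ref = anchor
        alt = anchor + "".join(bases[j] for j in ins_seq_idx[:ilen])
    raw = RawVariantRecord(chrom=chrom, pos=p0 + 1, ref=ref, alt=[alt])
    normed = normalize(raw, reference=reference)
    return normed[0] if normed else None


def _draw_afs(cfg, u, val, mult, jit, p_rare):
    """(af_gnomad, af_popmax, af_exac, af_1000g, af_max) or Nones."""
    if u < cfg.p_af_absent:
        return None, None, None, None, None
    if u < cfg.p_af_absent + p_rare:
        lo, hi = cfg.rare_af_range
    else:
        lo, hi = cfg.low_af_range
    a = float(np.exp(np.log(lo) + val * (np.log(hi) - np.log(lo))))
    af_gnomad = round(a, 8)
    af_popmax = round(min(a * float(mult), 0.5), 8)
    af_exac = round(min(a * float(jit[0]), 0.5), 8)
    af_1000g = round(min(a * float(jit[1]), 0.5), 8)
    af_max = max(af_gnomad, af_exac, af_1000g)
    return af_gnomad, af_popmax, af_exac, af_1000g, af_max


def _make_annotation(nv, gene: Gene, region: str, vt: str, clinvar: str,
                     af_gnomad, af_popmax, af_exac, af_1000g, af_max,
                     cadd) -> TranscriptAnnotation:
    terms = REGION_TERMS[(region, vt)]
    return TranscriptAnnotation(
        variant_key=nv.key, allele=nv.alt, gene_symbol=gene.name,
        transcript_id=gene.transcript_id, canonical=True,
        consequence_terms=tuple(terms),
        hgvs_c=f"c.{nv.pos % 9999 + 1}{nv.ref}>{nv.alt}" if vt == SNV
               else f"c.{nv.pos % 9999 + 1}del",
        clinvar_sig=parse_clinvar_labels(clinvar) if clinvar else frozenset(),
        af_gnomad=af_gnomad, af_popmax=af_popmax, af_max=af_max,
        af_exac=af_exac, af_1000g=af_1000g, cadd=cadd)


def _truth_row(cfg, sid, nv, asg, region, second_class, gene, panel,
               clinvar, qc_code, af_gnomad, af_popmax, af_exac, af_1000g,
               af_max, anns) -> dict:
    def absent(x):
        return x is None or (isinstance(x, float) and x != x)

    relevant = False
    if clinvar in ("pathogenic", "likely_pathogenic"):
        relevant = True
    elif clinvar == "uncertain_significance":
        relevant = absent(af_popmax) or af_popmax < 0.1
    passes_hard = qc_code not in _HARD_CODES
    passes_quality = qc_code not in _QUALITY_CODES
    pass_prefilter = absent(af_max) or af_max < 0.05
    sources = [a for a in (af_exac, af_1000g, af_gnomad) if not absent(a)]
    pass_af = (all(a < 0.01 for a in sources)
               and (absent(af_popmax) or af_popmax < 0.01))
    secondary_only = asg in (ASSIGN_B, ASSIGN_PADDING)
    in_secondary = asg != ASSIGN_A
    genes_hit = {gene.name} | ({anns[1].gene_symbol} if len(anns) > 1 else set())
    in_panel = bool(genes_hit & panel)
    survives = (in_secondary and passes_hard and passes_quality and pass_prefilter
                and pass_af and secondary_only and in_panel)
    tier = 0
    if survives:
        tier = 1 if nv.vtype == INDEL else (2 if region != "exonic" else 3)
    return {
        "sample": sid, "chrom": nv.chrom, "pos": nv.pos, "ref": nv.ref,
        "alt": nv.alt, "vtype": nv.vtype, "region_class": region,
        "second_region_class": second_class, "gene": gene.name,
        "n_units": 2 if second_class else 1, "pipelines": asg,
        "in_padding_only": asg == ASSIGN_PADDING, "clinvar": clinvar,
        "clinically_relevant": relevant, "qc_code": qc_code,
        "passes_hard": passes_hard, "passes_quality": passes_quality,
        "af_gnomad": af_gnomad, "af_popmax": af_popmax, "af_max": af_max,
        "pass_prefilter": pass_prefilter, "pass_af_stage": pass_af,
        "secondary_only": secondary_only, "in_panel": in_panel,
        "survives_cascade": survives, "tier": tier,
        "causal_scenario": "", "expected_status": "", "expected_reason": "",
    }


# ---------------------------------------------------------------------------
# Causal planting
# ---------------------------------------------------------------------------

def plant_causal(cfg: SimConfig, cohort: Cohort) -> Cohort:
    """Realize the configured causal scenarios in chosen samples.

    Expected audit outcomes recorded in the truth table assume the canonical
    audit configuration: padded regions, hard + quality filters and the
    diploidy (VAF) check active.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    samples = cohort.sample_ids
    panel_genes = [g for g in cohort.genes if g.in_panel]
    if not panel_genes:
        raise ValueError("no eligible panel gene for causal planting")
    records: list[CausalRecord] = []
    new_truth: list[dict] = []
    scenario_list = [name for name, count in cfg.causal_plan
                     for _ in range(count)]
    if len(scenario_list) > len(samples):
        raise ValueError("more causal scenarios than samples")
    for idx, scenario in enumerate(scenario_list):
        sid = samples[idx]
        gene = panel_genes[idx % len(panel_genes)]
        tgt = gene.intervals[idx % len(gene.intervals)]
        rec, row = _plant_one(cfg, cohort, rng, scenario, sid, gene, tgt)
        if rec is not None:
            records.append(rec)
        if row is not None:
            new_truth.append(row)
    cohort.causal_records.extend(records)
    if new_truth:
        cohort.truth = pd.concat(
            [cohort.truth, pd.DataFrame(new_truth)], ignore_index=True)
    return cohort


def _fresh_locus(cohort, sid, tgt, rng, indel_len=0, outside=0):
    """A position whose variant will not collide with existing INDEL spans."""
    occupied = set()
    for avs in (cohort.annotated_a.get(sid, []), cohort.annotated_b.get(sid, [])):
        for av in avs:
            if av.variant.vtype == INDEL:
                s = av.variant.span
                occupied.update(range(s.start - 1, s.end + 1))
    for _ in range(200):
        if outside:
            p0 = tgt.start - int(rng.integers(2, outside + 1))
        else:
            p0 = int(rng.integers(tgt.start + 10, tgt.end - 10))
        cells = set(range(p0 - 1, p0 + indel_len + 2))
        if cells & occupied:
            continue
        return p0
    raise ValueError("no eligible locus for causal planting")


def _plant_one(cfg, cohort, rng, scenario, sid, gene, tgt):
    reference = cohort.reference
    sample_a = cohort.annotated_a[sid]
    sample_b = cohort.annotated_b[sid]

    def build(p0, vt, is_del=True, ilen=2, outside=0):
        taken = ({v.variant.key for v in sample_b}
                 | {v.variant.key for v in sample_a})
        nv = None
        for _ in range(100):
            nv = _build_variant(reference, "1", p0, vt, is_del, ilen,
                                int(rng.integers(0, 3)),
                                rng.integers(0, 4, size=cfg.indel_max_len))
            if nv is not None and nv.key not in taken:
                break
            p0 = _fresh_locus(cohort, sid, tgt, rng, indel_len=ilen,
                              outside=outside)
        else:
            raise ValueError("no collision-free causal locus found")
        nv.qual = 900.0
        nv.filter = "PASS"
        nv.info = {"QD": 20.0, "MQ": 60.0, "MQRankSum": 0.0,
                   "ReadPosRankSum": 0.0, "DP": 120}
        nv.vaf = 0.5
        nv.sample_id = sid
        return nv

    def annotate(nv, region, clinvar="pathogenic"):
        vt = nv.vtype
        ann = _make_annotation(nv, gene, region, vt, clinvar,
                               None, None, None, None, None, 28.0)
        return AnnotatedVariant(variant=nv, annotations=[ann])

    def record(nv, vtype):
        ann_hgvs = f"c.{nv.pos % 9999 + 1}" + ("del" if vtype == INDEL
                                               else f"{nv.ref}>{nv.alt}")
        return CausalRecord(
            sample_id=sid, gene_symbol=gene.name,
            transcript_id=gene.transcript_id, hgvs_c=ann_hgvs, vtype=vtype,
            zygosity="HET",
            genomic_key=VariantKey(nv.chrom, nv.pos, nv.ref, nv.alt))

    def truth(nv, region, asg, status, reason, clinvar="pathogenic",
              survives=False, tier=0):
        nan = float("nan")
        row = _truth_row(cfg, sid, nv, asg, region, "", gene, cohort.panel,
                         clinvar, "", nan, nan, nan, nan, nan, [None])
        row.update({
            "causal_scenario": scenario, "expected_status": status,
            "expected_reason": reason, "survives_cascade": survives,
            "tier": tier,
        })
        return row

    if scenario == "found":
        p0 = _fresh_locus(cohort, sid, tgt, rng)
        nv = build(p0, SNV)
        av = annotate(nv, "exonic")
        sample_a.append(av)
        sample_b.append(av)
        return record(nv, SNV), truth(nv, "exonic", ASSIGN_BOTH, "found", "")

    if scenario == "padding_splice_snv":
        # 2-3 bp outside the target: detectable only with padding applied
        p0 = _fresh_locus(cohort, sid, tgt, rng, outside=3)
        nv = build(p0, SNV, outside=3)
        av = annotate(nv, "splicing")
        sample_b.append(av)
        row = truth(nv, "splicing", ASSIGN_PADDING, "found", "",
                    survives=True, tier=2)
        return record(nv, SNV), row

    if scenario == "second_allele_exonic_indel":
        p0 = _fresh_locus(cohort, sid, tgt, rng, indel_len=2)
        nv = build(p0, INDEL, is_del=True, ilen=2)
        av = annotate(nv, "exonic")
        sample_b.append(av)
        row = truth(nv, "exonic", ASSIGN_B, "found", "",
                    survives=True, tier=1)
        return record(nv, INDEL), row

    if scenario == "low_vaf_snv":
        p0 = _fresh_locus(cohort, sid, tgt, rng)
        nv = build(p0, SNV)
        nv.vaf = 0.18
        av = annotate(nv, "exonic")
        sample_a.append(av)
        sample_b.append(av)
        return record(nv, SNV), truth(nv, "exonic", ASSIGN_BOTH,
                                      "missed", "low_vaf")

    if scenario == "hard_filter_fail":
        p0 = _fresh_locus(cohort, sid, tgt, rng)
        nv = build(p0, SNV)
        nv.info["MQ"] = 30.0
        av = annotate(nv, "exonic")
        sample_a.append(av)
        sample_b.append(av)
        row = truth(nv, "exonic", ASSIGN_BOTH, "missed", "hard_filter_fail")
        row["qc_code"] = "SNP_MQ"
        row["passes_hard"] = False
        return record(nv, SNV), row

    if scenario == "absent_from_calls":
        # the record exists in the diagnostic table, the call does not
        p0 = _fresh_locus(cohort, sid, tgt, rng)
        nv = build(p0, SNV)
        rec = record(nv, SNV)
        row = truth(nv, "exonic", ASSIGN_A, "missed", "absent_from_calls")
        row["pipelines"] = "none"
        row["secondary_only"] = False
        row["survives_cascade"] = False
        return rec, row

    raise ValueError(f"unknown causal scenario {scenario!r}")


def simulate(cfg: Optional[SimConfig] = None) -> Cohort:
    """gen_targets + gen_cohort + plant_causal under one seed."""
    cfg = cfg or SimConfig()
    return plant_causal(cfg, gen_cohort(cfg))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Emit the cohort as files: FASTA, BED, per-sample VCFs, panel, truth.

    Layout: reference.fa, targets.bed, panel.txt, causal.tsv, truth.tsv,
    commercial/<sample>.vcf, secondary/<sample>.vcf.
    """
    from .vcfio import write_fasta, write_vcf

    out = Path(outdir)
    (out / "commercial").mkdir(parents=True, exist_ok=True)
    (out / "secondary").mkdir(parents=True, exist_ok=True)
    ref_path = out / "reference.fa"
    write_fasta({c: cohort.reference.fetch(c, 0, length)
                 for c, length in cohort.contig_lengths.items()}, ref_path)
    bed_path = out / "targets.bed"
    cohort.targets.to_bed(bed_path)
    panel_path = out / "panel.txt"
    with open(panel_path, "w") as fh:
        fh.write("# virtual gene panel\n")
        for g in sorted(cohort.panel):
            fh.write(g + "\n")
    for sid in cohort.sample_ids:
        for side, annotated in (("commercial", cohort.annotated_a),
                                ("secondary", cohort.annotated_b)):
            write_vcf(annotated[sid], out / side / f"{sid}.vcf", sid,
                      cohort.contig_lengths, cohort.csq_fields)
    causal_path = out / "causal.tsv"
    write_causal_table(cohort.causal_records, causal_path)
    truth_path = out / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    with open(out / "simconfig.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2, default=list)
    return {"reference": ref_path, "bed": bed_path, "panel": panel_path,
            "causal": causal_path, "truth": truth_path, "outdir": out}
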