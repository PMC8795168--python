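"""File-format I/O: VCF (cyvcf2), FASTA (pyfaidx) and normalized TSV tables.

Reading goes through cyvcf2 and converts each record into the package's
normalized representation on ingest; the annotation INFO key (default "CSQ")
and its field format are discovered from the VCF header.  Writing emits plain
VCF v4.2 text with enough header to round-trip through the same reader.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

from .annotation import AnnotatedVariant, parse_csq
from .variantcore import (DictReference, NormalizedVariant, RawVariantRecord,
                          SymbolicAlleleError, normalize, normalize_chrom)

log = logging.getLogger(__name__)

_METRIC_KEYS = ("QD", "MQ", "MQRankSum", "ReadPosRankSum", "DP")


class FastaReference:
    """pyfaidx-backed reference with 0-based half-open fetch."""

    def __init__(self, path) -> None:
        from pyfaidx import Fasta
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self._names = {normalize_chrom(n): n for n in self._fa.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        name = self._names.get(normalize_chrom(chrom))
        if name is None:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        return str(self._fa[name][max(0, start):end])


def read_fasta(path) -> DictReference:
    """Load a (small) FASTA into an in-memory reference."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return DictReference({n: "".join(parts) for n, parts in seqs.items()})


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def csq_format_from_header(vcf: VCF, info_key: str = "CSQ") -> Optional[list[str]]:
    """Extract the annotation field-name list from the header description."""
    try:
        desc = vcf.get_header_type(info_key).get("Description", "")
    except KeyError:
        return None
    m = re.search(r"Format:\s*([\w|]+)", desc.strip('" '))
    return m.group(1).split("|") if m else None


def read_vcf(
    path,
    reference=None,
    sample_id: Optional[str] = None,
    info_key: str = "CSQ",
    window: int = 200,
) -> list[AnnotatedVariant]:
    """Read, decompose and normalize a VCF into annotated variants.

    ``sample_id`` defaults to the single sample name in the file (or the file
    stem for site-only VCFs).  Symbolic-allele records are skipped with a
    warning.  Annotations are parsed from ``info_key`` when both the key and
    its header format are present.
    """
    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    csq_fields = csq_format_from_header(vcf, info_key)
    out: list[AnnotatedVariant] = []
    for rec in vcf:
        metrics = {}
        for k in _METRIC_KEYS:
            v = rec.INFO.get(k)
            if v is not None:
                metrics[k] = float(v)
        ad = None
        gt = None
        if vcf.samples:
            try:
                ad_arr = rec.format("AD")
                if ad_arr is not None:
                    ad = [int(x) for x in ad_arr[0] if x >= 0]
            except KeyError:
                ad = None
            gts = rec.genotypes
            if gts:
                g = gts[0]
                gt = "/".join(str(a) for a in g[:-1])
        raw = RawVariantRecord(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=list(rec.ALT),
            qual=rec.QUAL, filter=rec.FILTER or "PASS", info_metrics=metrics,
            sample_gt=gt, allele_depths=ad, sample_id=sample_id)
        try:
            normed = normalize(raw, reference=reference, window=window)
        except SymbolicAlleleError as exc:
            log.warning("skipping record: %s", exc)
            continue
        csq_val = rec.INFO.get(info_key) if csq_fields else None
        for nv in normed:
            anns = []
            if csq_val:
                anns = [a for a in parse_csq(csq_val, csq_fields, nv.key)
                        if a.allele is None or a.allele == nv.alt]
            out.append(AnnotatedVariant(variant=nv, annotations=anns))
    vcf.close()
    return out


def load_calls(
    path, reference=None, sample_id: Optional[str] = None, **kw
) -> list[NormalizedVariant]:
    """Normalized variants only (annotations discarded)."""
    return [av.variant for av in read_vcf(path, reference, sample_id, **kw)]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score From Wilcoxon rank sum test of Alt vs. Ref read mapping qualities">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">',
    '##FILTER=<ID=SNP_filter,Description="SNV hard filter">',
    '##FILTER=<ID=INDEL_filter,Description="INDEL hard filter">',
    '##FILTER=<ID=LowQual,Description="Low quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">',
]


def _fmt_float(x: float) -> str:
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_vcf(
    variants: Iterable[AnnotatedVariant],
    path,
    sample_id: str,
    contig_lengths: Mapping[str, int],
    csq_fields: Optional[Sequence[str]] = None,
    info_key: str = "CSQ",
) -> None:
    """Write annotated variants as sorted plain VCF v4.2 text."""
    from .annotation import format_csq

    lines = ["##fileformat=VCFv4.2", "##source=reanalyzer"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_VCF_HEADER_LINES)
    if csq_fields:
        fmt = "|".join(csq_fields)
        lines.append(
            f'##INFO=<ID={info_key},Number=.,Type=String,'
            f'Description="Consequence annotations. Format: {fmt}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample_id)

    recs = sorted(variants, key=lambda av: (av.variant.chrom, av.variant.pos,
                                            av.variant.ref, av.variant.alt))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for av in recs:
            v = av.variant
            info_parts = []
            for k in _METRIC_KEYS:
                if k in v.info:
                    val = v.info[k]
                    info_parts.append(
                        f"{k}={int(val)}" if k == "DP" else f"{k}={_fmt_float(val)}")
            if csq_fields and av.annotations:
                info_parts.append(
                    f"{info_key}={format_csq(av.annotations, csq_fields)}")
            dp = int(v.info.get("DP", 0))
            if v.vaf is not None and dp:
                alt_d = round(v.vaf * dp)
                ad = f"{dp - alt_d},{alt_d}"
                gt = "1/1" if v.vaf > 0.85 else "0/1"
            else:
                ad = "."
                gt = "0/1"
            qual = _fmt_float(v.qual) if v.qual is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t"
                f"{v.filter}\t{';'.join(info_parts) or '.'}\t"
                f"GT:AD:DP\t{gt}:{ad}:{dp}\n")


def write_normalized_tsv(variants: Iterable[NormalizedVariant], path) -> None:
    """Normalized variant table: chrom, pos, ref, alt, vtype, qual, filter, DP, VAF."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvtype\tqual\tfilter\tDP\tVAF\n")
        for v in variants:
            qual = _fmt_float(v.qual) if v.qual is not None else ""
            dp = int(v.info["DP"]) if "DP" in v.info else ""
            vaf = _fmt_float(v.vaf) if v.vaf is not None else ""
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vtype}\t"
                     f"{qual}\t{v.filter}\t{dp}\t{vaf}\n")
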