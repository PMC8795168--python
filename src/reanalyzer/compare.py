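"""Pairwise pipeline comparison.

Common/unique variant accounting (Venn), per-sample stratified counts by
variant type and genomic region, clinically relevant subsetting, and the
comparison statistics (two-sided Fisher exact test on summed 2x2 counts and
Welch's t-test on per-sample counts, over a seeded subsample of samples).

Inputs are per-sample lists of normalized variants (pipeline A = the primary
commercial analysis, pipeline B = the in-house reanalysis pipeline); fold
changes are oriented B over A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotatedVariant, is_clinically_relevant, select_canonical
from .variantcore import (EXACT, MATCH_MODES, NormalizedVariant, TargetRegions,
                          in_regions, match_flags)

log = logging.getLogger(__name__)

COUNT_COLUMNS = ("sample", "vtype", "region_class", "count")


class SampleMismatchError(ValueError):
    """The two call sets do not cover the same samples."""


@dataclass
class SampleVenn:
    sample_id: str
    n_common: int
    n_only_a: int
    n_only_b: int
    n_matched_b: int  # B-side matched count (== n_common in exact mode)

    @property
    def n_a(self) -> int:
        return self.n_common + self.n_only_a

    @property
    def n_b(self) -> int:
        return self.n_matched_b + self.n_only_b


@dataclass
class PipelineComparison:
    """Cohort-level Venn accounting for two pipelines.

    ``n_common`` is the A-side matched count summed over samples; in exact
    match mode it equals the B-side matched count, under overlap matching the
    two sides can differ and ``n_matched_b`` carries the B-side figure.
    Conservation: n_common + n_only_a = total distinct normalized variants of
    pipeline A; n_matched_b + n_only_b = same for B.
    """

    sample_ids: tuple[str, ...]
    per_sample: list[SampleVenn]
    padding_mode: str  # "none" | "padded"
    match_mode: str
    common_variants: Optional[dict[str, list[NormalizedVariant]]] = None
    only_a_variants: Optional[dict[str, list[NormalizedVariant]]] = None
    only_b_variants: Optional[dict[str, list[NormalizedVariant]]] = None

    @property
    def n_common(self) -> int:
        return sum(s.n_common for s in self.per_sample)

    @property
    def n_matched_b(self) -> int:
        return sum(s.n_matched_b for s in self.per_sample)

    @property
    def n_only_a(self) -> int:
        return sum(s.n_only_a for s in self.per_sample)

    @property
    def n_only_b(self) -> int:
        return sum(s.n_only_b for s in self.per_sample)

    def venn_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "n_only_a": self.n_only_a,
            "n_only_b": self.n_only_b,
            "n_matched_b": self.n_matched_b,
            "padding_mode": self.padding_mode,
            "match_mode": self.match_mode,
            "n_samples": len(self.sample_ids),
        }


def _dedupe(variants: Sequence[NormalizedVariant]) -> list[NormalizedVariant]:
    seen = set()
    out = []
    for v in variants:
        if v.key not in seen:
            seen.add(v.key)
            out.append(v)
    return out


def compare_pair(
    calls_a: Mapping[str, Sequence[NormalizedVariant]],
    calls_b: Mapping[str, Sequence[NormalizedVariant]],
    regions: Optional[TargetRegions] = None,
    match_mode: str = EXACT,
    keep_variants: bool = False,
) -> PipelineComparison:
    """Per-sample common/unique variant accounting for two pipelines.

    Variant sets are restricted to ``regions`` (when given) via partial-overlap
    interval intersection, de-duplicated on the exact key, then matched per
    ``match_mode``.  Raises :class:`SampleMismatchError` when the sample sets
    differ.
    """
    if match_mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {match_mode!r}")
    missing_a = sorted(set(calls_b) - set(calls_a))
    missing_b = sorted(set(calls_a) - set(calls_b))
    if missing_a or missing_b:
        raise SampleMismatchError(
            f"samples missing from A: {missing_a}; missing from B: {missing_b}")

    per_sample = []
    common: dict[str, list[NormalizedVariant]] = {}
    only_a: dict[str, list[NormalizedVariant]] = {}
    only_b: dict[str, list[NormalizedVariant]] = {}
    samples = tuple(sorted(calls_a))
    for sid in samples:
        va = _dedupe(calls_a[sid])
        vb = _dedupe(calls_b[sid])
        if regions is not None:
            va = [v for v in va if in_regions(v, regions)]
            vb = [v for v in vb if in_regions(v, regions)]
        fa, fb = match_flags(va, vb, match_mode)
        n_matched_a = sum(fa)
        n_matched_b = sum(fb)
        per_sample.append(SampleVenn(
            sample_id=sid,
            n_common=n_matched_a,
            n_only_a=len(va) - n_matched_a,
            n_only_b=len(vb) - n_matched_b,
            n_matched_b=n_matched_b,
        ))
        if keep_variants:
            common[sid] = [v for v, f in zip(va, fa) if f]
            only_a[sid] = [v for v, f in zip(va, fa) if not f]
            only_b[sid] = [v for v, f in zip(vb, fb) if not f]

    padding_mode = "padded" if regions is not None and regions.padded else "none"
    return PipelineComparison(
        sample_ids=samples,
        per_sample=per_sample,
        padding_mode=padding_mode,
        match_mode=match_mode,
        common_variants=common if keep_variants else None,
        only_a_variants=only_a if keep_variants else None,
        only_b_variants=only_b if keep_variants else None,
    )


# ---------------------------------------------------------------------------
# Stratified counting
# ---------------------------------------------------------------------------

def stratified_counts(
    annotated: Mapping[str, Sequence[AnnotatedVariant]],
) -> pd.DataFrame:
    """Per-(sample, vtype, region_class) counts over canonical annotations.

    Counting unit is the (variant, gene) canonical pair: a variant canonical
    in two genes contributes one count to each gene's region class.  Samples
    with no qualifying variants appear with an all-zero row so cohort means
    include them.
    """
    return _counts(annotated, relevant_only=False)


def clinically_relevant_counts(
    annotated: Mapping[str, Sequence[AnnotatedVariant]],
    popmax_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Stratified counts restricted to the clinically relevant subset."""
    return _counts(annotated, relevant_only=True, popmax_cutoff=popmax_cutoff)


def _counts(annotated, relevant_only: bool, popmax_cutoff: float = 0.1,
            ) -> pd.DataFrame:
    rows: dict[tuple, int] = {}
    empty_samples = []
    for sid, avs in annotated.items():
        any_row = False
        for av in avs:
            for ann in select_canonical(av):
                if relevant_only and not is_clinically_relevant(
                        ann, popmax_cutoff=popmax_cutoff):
                    continue
                key = (sid, av.variant.vtype, ann.region_class)
                rows[key] = rows.get(key, 0) + 1
                any_row = True
        if not any_row:
            empty_samples.append(sid)
    df = pd.DataFrame(
        [(s, t, r, c) for (s, t, r), c in rows.items()],
        columns=list(COUNT_COLUMNS),
    )
    if empty_samples:
        zeros = pd.DataFrame(
            [(s, "SNV", "exonic", 0) for s in empty_samples],
            columns=list(COUNT_COLUMNS),
        )
        df = pd.concat([df, zeros], ignore_index=True)
    return df.sort_values(list(COUNT_COLUMNS[:3])).reset_index(drop=True)


def cohort_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of per-sample counts per (vtype, region).

    Samples absent from a cell count as zero for that cell.
    """
    n_samples = counts["sample"].nunique()
    g = (counts.groupby(["vtype", "region_class"])["count"]
         .agg(total="sum", nonzero="count"))
    # mean over all samples, treating absences as zeros
    g["mean"] = g["total"] / n_samples
    sq = (counts.assign(sq=counts["count"] ** 2)
          .groupby(["vtype", "region_class"])["sq"].sum())
    var = sq / n_samples - g["mean"] ** 2
    g["std"] = np.sqrt(np.maximum(var, 0.0))
    return g[["mean", "std", "total"]].reset_index()


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatTestResult:
    category: tuple
    fold_change: float  # mean_B / mean_A over the subsample
    p_value: float
    test_name: str  # "fisher" | "welch_t"
    n_subsampled: int
    seed: int
    stars: str = ""
    flagged: bool = False


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _per_sample_matrix(counts: pd.DataFrame, by_region: bool) -> pd.DataFrame:
    keys = ["vtype", "region_class"] if by_region else ["vtype"]
    return counts.pivot_table(index="sample", columns=keys, values="count",
                              aggfunc="sum", fill_value=0)


def subsample_and_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    n: int = 100,
    seed: int = 42,
    tests: Sequence[str] = ("fisher", "welch_t"),
) -> list[StatTestResult]:
    """Seeded subsampled comparison of per-sample count distributions.

    Draws ``n`` samples per pipeline without replacement (all samples, with a
    warning, when fewer are available), then per category — variant type, and
    variant type x region class — computes (a) a two-sided Fisher exact test
    on the 2x2 table of summed in-category vs out-of-category counts, and
    (b) Welch's t-test on the per-sample counts; fold change is
    mean_B / mean_A over the subsample.  Zero-variance, equal-mean t-tests
    yield p = 1 by convention and are flagged.
    """
    rng = np.random.default_rng(seed)
    results: list[StatTestResult] = []
    for by_region in (False, True):
        mat_a = _per_sample_matrix(counts_a, by_region)
        mat_b = _per_sample_matrix(counts_b, by_region)
        sub_a = _draw(mat_a, n, rng, "A")
        sub_b = _draw(mat_b, n, rng, "B")
        categories = sorted(set(sub_a.columns) | set(sub_b.columns))
        tot_a = int(sub_a.to_numpy().sum())
        tot_b = int(sub_b.to_numpy().sum())
        for cat in categories:
            in_a = sub_a[cat] if cat in sub_a.columns else pd.Series(
                0, index=sub_a.index)
            in_b = sub_b[cat] if cat in sub_b.columns else pd.Series(
                0, index=sub_b.index)
            mean_a, mean_b = float(in_a.mean()), float(in_b.mean())
            fc = mean_b / mean_a if mean_a > 0 else float("nan")
            cat_key = cat if isinstance(cat, tuple) else (cat,)
            if "fisher" in tests:
                sa, sb = int(in_a.sum()), int(in_b.sum())
                table = [[sa, tot_a - sa], [sb, tot_b - sb]]
                _, p = sps.fisher_exact(table, alternative="two-sided")
                results.append(StatTestResult(
                    cat_key, fc, float(p), "fisher", len(sub_a), seed,
                    significance_stars(float(p))))
            if "welch_t" in tests:
                flagged = False
                if in_a.std() == 0 and in_b.std() == 0:
                    p = 1.0 if mean_a == mean_b else 0.0
                    flagged = True
                else:
                    _, p = sps.ttest_ind(in_b, in_a, equal_var=False)
                    p = float(p)
                results.append(StatTestResult(
                    cat_key, fc, p, "welch_t", len(sub_a), seed,
                    significance_stars(p), flagged))
    return results


def _draw(mat: pd.DataFrame, n: int, rng: np.random.Generator,
          label: str) -> pd.DataFrame:
    if len(mat) < n:
        log.warning("only %d samples available in set %s (requested %d); "
                    "using all", len(mat), label, n)
        return mat
    idx = rng.choice(len(mat), size=n, replace=False)
    return mat.iloc[np.sort(idx)]


def results_table(results: Sequence[StatTestResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "category": "/".join(map(str, r.category)),
            "test": r.test_name,
            "fold_change": r.fold_change,
            "p_value": r.p_value,
            "stars": r.stars,
            "n_subsampled": r.n_subsampled,
            "seed": r.seed,
            "flagged": r.flagged,
        }
        for r in results
    ])
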