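"""Venn accounting, stratified counting and comparison statistics."""

from math import comb

import pandas as pd
import pytest

from reanalyzer.annotation import AnnotatedVariant, TranscriptAnnotation
from reanalyzer.compare import (SampleMismatchError, clinically_relevant_counts,
                                cohort_summary, compare_pair,
                                significance_stars, stratified_counts,
                                subsample_and_test)
from reanalyzer.variantcore import NormalizedVariant, variant_type


def _nv(pos, ref="A", alt="G", sample="S1"):
    vt, mnv = variant_type(ref, alt)
    return NormalizedVariant(chrom="1", pos=pos, ref=ref, alt=alt, vtype=vt,
                             qual=500.0, filter="PASS", info={}, vaf=None,
                             sample_id=sample, mnv=mnv)


def _av(pos, ref="A", alt="G", sample="S1", gene="G1", terms=("missense_variant",),
        canonical=True, clinvar=frozenset(), popmax=None):
    nv = _nv(pos, ref, alt, sample)
    ann = TranscriptAnnotation(gene_symbol=gene, transcript_id=f"NM_{gene}",
                               canonical=canonical,
                               consequence_terms=tuple(terms),
                               clinvar_sig=clinvar, af_popmax=popmax)
    return AnnotatedVariant(variant=nv, annotations=[ann])


# ---------------------------------------------------------------------------
# compare_pair
# ---------------------------------------------------------------------------

def test_identical_call_sets_have_no_unique_variants():
    calls = {"S1": [_nv(10), _nv(20), _nv(30, "CA", "C")]}
    res = compare_pair(calls, calls)
    assert (res.n_common, res.n_only_a, res.n_only_b) == (3, 0, 0)


def test_sample_mismatch_raises_with_names():
    with pytest.raises(SampleMismatchError, match="S2"):
        compare_pair({"S1": []}, {"S1": [], "S2": []})


def test_venn_counts_equal_generator_truth(small_cohort):
    t = small_cohort.truth
    calls_a, calls_b = small_cohort.calls_a(), small_cohort.calls_b()
    for regions, include_padding in ((small_cohort.targets, False),
                                     (small_cohort.padded_targets, True)):
        res = compare_pair(calls_a, calls_b, regions, "exact")
        tt = t[t.pipelines != "none"]
        if not include_padding:
            tt = tt[~tt.in_padding_only.astype(bool)]
        assert res.n_common == (tt.pipelines == "both").sum()
        assert res.n_only_a == (tt.pipelines == "a_only").sum()
        assert res.n_only_b == tt.pipelines.isin(
            ["b_only", "padding_only"]).sum()
        # conservation: every variant of A is common or A-only
        for sv in res.per_sample:
            assert sv.n_common + sv.n_only_a == sv.n_a
            assert sv.n_matched_b + sv.n_only_b == sv.n_b


def test_padding_only_variants_appear_only_with_padding(small_cohort):
    t = small_cohort.truth
    planted = (t.in_padding_only.astype(bool) & (t.pipelines != "none")).sum()
    res_np = compare_pair(small_cohort.calls_a(), small_cohort.calls_b(),
                          small_cohort.targets)
    res_p = compare_pair(small_cohort.calls_a(), small_cohort.calls_b(),
                         small_cohort.padded_targets)
    assert res_p.n_only_b - res_np.n_only_b == planted


def test_padding_monotonicity(small_cohort):
    res_np = compare_pair(small_cohort.calls_a(), small_cohort.calls_b(),
                          small_cohort.targets)
    res_p = compare_pair(small_cohort.calls_a(), small_cohort.calls_b(),
                         small_cohort.padded_targets)
    for a, b in zip(res_np.per_sample, res_p.per_sample):
        assert b.n_a >= a.n_a and b.n_b >= a.n_b


# ---------------------------------------------------------------------------
# stratified counting
# ---------------------------------------------------------------------------

def test_stratified_counts_basic():
    annotated = {"S1": [
        _av(10), _av(20), _av(30),                      # 3 exonic SNVs
        _av(40, "CA", "C", terms=("intron_variant",)),  # 1 intronic INDEL
    ], "S2": []}
    df = stratified_counts(annotated)
    cells = {(r["sample"], r.vtype, r.region_class): r["count"]
             for _, r in df.iterrows() if r["count"] > 0}
    assert cells == {("S1", "SNV", "exonic"): 3, ("S1", "INDEL", "intronic"): 1}
    # the empty sample still contributes a zero row for cohort means
    assert set(df["sample"]) == {"S1", "S2"}
    summary = cohort_summary(df)
    exonic = summary[(summary.vtype == "SNV")
                     & (summary.region_class == "exonic")].iloc[0]
    assert exonic["mean"] == pytest.approx(1.5)  # (3 + 0) / 2 samples


def test_multi_gene_canonical_variant_counts_in_each_class():
    nv = _nv(10)
    anns = [
        TranscriptAnnotation(gene_symbol="A", transcript_id="NM_1",
                             canonical=True,
                             consequence_terms=("missense_variant",)),
        TranscriptAnnotation(gene_symbol="B", transcript_id="NM_2",
                             canonical=True,
                             consequence_terms=("5_prime_UTR_variant",)),
    ]
    df = stratified_counts({"S1": [AnnotatedVariant(nv, anns)]})
    cells = {(r.vtype, r.region_class): r["count"]
             for _, r in df.iterrows() if r["count"] > 0}
    assert cells == {("SNV", "exonic"): 1, ("SNV", "utr5"): 1}


def test_clinically_relevant_subset():
    annotated = {"S1": [
        _av(10, clinvar=frozenset({"pathogenic"})),
        _av(20, clinvar=frozenset({"uncertain_significance"}), popmax=0.5),
        _av(30),  # no ClinVar record
    ]}
    df = clinically_relevant_counts(annotated)
    assert df["count"].sum() == 1  # only the pathogenic variant counts


def test_relevant_counts_bounded_by_stratified(small_cohort):
    full = stratified_counts(small_cohort.annotated_b)
    rel = clinically_relevant_counts(small_cohort.annotated_b)
    merged = full.merge(rel, on=["sample", "vtype", "region_class"],
                        how="outer", suffixes=("_all", "_rel")).fillna(0)
    assert (merged["count_rel"] <= merged["count_all"]).all()


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(table):
    """Exact two-sided Fisher p by hypergeometric enumeration (oracle)."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    def pk(k):
        return comb(row1, k) * comb(row2, col1 - k) / denom
    p_obs = pk(a)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    return sum(pk(k) for k in range(lo, hi + 1) if pk(k) <= p_obs * (1 + 1e-9))


def _counts_df(sample_cells):
    rows = [(s, vt, rc, n) for s, cells in sample_cells.items()
            for (vt, rc), n in cells.items()]
    return pd.DataFrame(rows, columns=["sample", "vtype", "region_class",
                                       "count"])


@pytest.mark.parametrize("tab", [
    [[10, 10], [10, 10]],
    [[12, 3], [4, 11]],
    [[1, 20], [15, 2]],
    [[0, 9], [7, 4]],
    [[25, 25], [20, 30]],
])
def test_fisher_pvalues_match_enumeration_oracle(tab):
    (a, b), (c, d) = tab
    counts_a = _counts_df({"A1": {("SNV", "exonic"): a, ("INDEL", "exonic"): b}})
    counts_b = _counts_df({"B1": {("SNV", "exonic"): c, ("INDEL", "exonic"): d}})
    results = subsample_and_test(counts_a, counts_b, n=1, seed=1,
                                 tests=("fisher",))
    snv = [r for r in results if r.category == ("SNV",)][0]
    assert snv.p_value == pytest.approx(fisher_two_sided_enumeration(tab),
                                        rel=1e-9)


def test_identical_counts_give_unit_fold_change_and_p():
    cells = {("SNV", "exonic"): 10, ("INDEL", "exonic"): 10}
    counts = _counts_df({"S1": cells, "S2": cells})
    results = subsample_and_test(counts, counts, n=2, seed=0)
    for r in results:
        assert r.fold_change == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)
        if r.test_name == "welch_t":
            assert r.flagged  # zero variance, equal means


def test_subsampled_tests_are_deterministic(small_cohort):
    ca = stratified_counts(small_cohort.annotated_a)
    cb = stratified_counts(small_cohort.annotated_b)
    r1 = subsample_and_test(ca, cb, n=5, seed=42)
    r2 = subsample_and_test(ca, cb, n=5, seed=42)
    assert r1 == r2
    assert all(r.seed == 42 for r in r1)


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
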