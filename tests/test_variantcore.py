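"""Normalization, matching and target-region arithmetic."""

import pytest
from hypothesis import given, strategies as st

from reanalyzer.variantcore import (EXACT, INDEL, OVERLAP_INDEL, SNV,
                                    DictReference, GenomicInterval,
                                    NormalizedVariant, RawVariantRecord,
                                    SymbolicAlleleError, TargetRegions,
                                    classify_type, in_regions, match,
                                    match_flags, normalize, pad_regions,
                                    variant_type)


def _nv(chrom, pos, ref, alt, **kw):
    vt, mnv = variant_type(ref, alt)
    defaults = dict(qual=500.0, filter="PASS", info={}, vaf=None,
                    sample_id="S", mnv=mnv)
    defaults.update(kw)
    return NormalizedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             vtype=vt, **defaults)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def brute_force_leftmost(window: str, win_start: int, pos: int, ref: str,
                         alt: str):
    """Independent oracle: enumerate every (pos, ref, alt) representation
    that yields the same alternate haplotype within the context window, trim
    each to its minimal anchored form, and return the left-most one."""
    p = pos - 1 - win_start  # 1-based pos -> 0-based offset into window
    hap = window[:p] + alt + window[p + len(ref):]
    reps = set()
    for q in range(len(window) + 1):
        if window[:q] != hap[:q]:
            break
        for lr in range(0, len(window) - q + 1):
            la = len(hap) - len(window) + lr
            if la < 0:
                continue
            r = window[q:q + lr]
            a = hap[q:q + la]
            if not r or not a or r == a:
                continue
            if window[q + lr:] != hap[q + la:]:
                continue
            # trim to minimal anchored form
            qq, rr, aa = q, r, a
            while len(rr) > 1 and len(aa) > 1 and rr[-1] == aa[-1]:
                rr, aa = rr[:-1], aa[:-1]
            while len(rr) > 1 and len(aa) > 1 and rr[0] == aa[0]:
                rr, aa = rr[1:], aa[1:]
                qq += 1
            reps.add((qq, rr, aa))
    assert reps, "oracle found no valid representation"
    q, r, a = min(reps, key=lambda t: (t[0], len(t[1]) + len(t[2])))
    return q + win_start + 1, r, a  # back to 1-based


def test_snv_already_minimal(toy_reference):
    raw = RawVariantRecord(chrom="chr1", pos=100, ref="A", alt=["G"])
    out = normalize(raw, toy_reference)
    assert len(out) == 1
    v = out[0]
    assert (v.chrom, v.pos, v.ref, v.alt, v.vtype) == ("1", 100, "A", "G", SNV)


def test_homopolymer_deletion_left_aligns_to_oracle():
    # context ...GCAAAAT...: a 1-bp deletion inside the A-run must land on
    # the unique left-most minimal representation
    seq = "GGGGGCAAAAATGGGG"
    ref = DictReference({"1": seq})
    for pos, r, a in [(7, "AA", "A"), (9, "AA", "A"), (6, "CAA", "CA"),
                      (10, "AAT", "AT")]:
        out = normalize(RawVariantRecord(chrom="1", pos=pos, ref=r, alt=[a]),
                        ref)
        v = out[0]
        exp = brute_force_leftmost(seq, 0, pos, r, a)
        assert (v.pos, v.ref, v.alt) == exp
        assert (v.pos, v.ref, v.alt) == (6, "CA", "C")


@given(st.data())
def test_normalization_matches_brute_force_oracle(data):
    rng = data.draw(st.randoms(use_true_random=False))
    seq = "".join(rng.choice("ACGT") for _ in range(60))
    ref = DictReference({"1": seq})
    p = rng.randrange(20, 40)
    if rng.random() < 0.5:  # deletion, possibly non-left-aligned
        ln = rng.randrange(1, 5)
        r, a = seq[p - 1:p + ln], seq[p - 1]
    else:  # insertion
        ins = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
        r, a = seq[p - 1], seq[p - 1] + ins
    # pad both alleles with shared flanking reference bases (equivalent rep)
    lpad = rng.randrange(0, 3)
    left = seq[p - 1 - lpad:p - 1]
    right = seq[p - 1 + len(r):p - 1 + len(r) + rng.randrange(0, 3)]
    raw = RawVariantRecord(chrom="1", pos=p - lpad, ref=left + r + right,
                           alt=[left + a + right])
    v = normalize(raw, ref)[0]
    assert (v.pos, v.ref, v.alt) == brute_force_leftmost(
        seq, 0, raw.pos, raw.ref, raw.alt[0])


def test_multiallelic_decomposition(toy_reference):
    raw = RawVariantRecord(chrom="1", pos=100, ref="A", alt=["G", "T"],
                           allele_depths=[50, 30, 20])
    out = normalize(raw, toy_reference)
    assert [(v.pos, v.alt) for v in out] == [(100, "G"), (100, "T")]
    assert out[0].vaf == pytest.approx(0.3)
    assert out[1].vaf == pytest.approx(0.2)


def test_normalize_is_idempotent(small_cohort):
    ref = small_cohort.reference
    sid = small_cohort.sample_ids[0]
    for av in small_cohort.annotated_b[sid]:
        v = av.variant
        raw = RawVariantRecord(chrom=v.chrom, pos=v.pos, ref=v.ref,
                               alt=[v.alt])
        again = normalize(raw, ref)[0]
        assert (again.pos, again.ref, again.alt) == (v.pos, v.ref, v.alt)


def test_symbolic_alleles_rejected(toy_reference):
    with pytest.raises(SymbolicAlleleError):
        normalize(RawVariantRecord(chrom="1", pos=10, ref="A", alt=["<DEL>"]),
                  toy_reference)
    with pytest.raises(SymbolicAlleleError):
        normalize(RawVariantRecord(chrom="1", pos=10, ref="A",
                                   alt=["A[2:321682["]), toy_reference)
    # spanning-deletion allele is skipped, not fatal
    out = normalize(RawVariantRecord(chrom="1", pos=10, ref="A",
                                     alt=["*", "G"]), toy_reference)
    assert [v.alt for v in out] == ["G"]


def test_trim_only_without_reference(caplog):
    out = normalize(RawVariantRecord(chrom="1", pos=10, ref="CAA", alt=["CA"]))
    v = out[0]
    assert (v.pos, v.ref, v.alt) == (10, "CA", "C")


# ---------------------------------------------------------------------------
# Type classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alt,vtype,mnv", [
    ("A", "G", SNV, False),
    ("CA", "C", INDEL, False),
    ("C", "CTT", INDEL, False),
    ("AT", "GC", INDEL, True),  # non-trimmable MNV classifies as INDEL
])
def test_classify_type(ref, alt, vtype, mnv):
    v = _nv("1", 100, ref, alt)
    assert classify_type(v) == vtype
    assert v.mnv == mnv


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def test_match_examples():
    a = _nv("1", 100, "CA", "C")
    b = _nv("1", 100, "CA", "C")
    assert match(a, b, EXACT) and match(a, b, OVERLAP_INDEL)

    # overlapping deletions: spans [99,104) and [101,104) share bases
    a = _nv("13", 100, "ATTTG", "A")
    b = _nv("13", 102, "TTG", "T")
    assert a.span.overlaps(b.span)
    assert match(a, b, OVERLAP_INDEL) and match(b, a, OVERLAP_INDEL)
    assert not match(a, b, EXACT)

    # distinct SNVs never match
    a = _nv("1", 100, "A", "G")
    b = _nv("1", 101, "A", "G")
    assert not match(a, b, EXACT) and not match(a, b, OVERLAP_INDEL)

    # SNV inside a deletion span is still not the same variant
    d = _nv("1", 99, "GAAA", "G")
    s = _nv("1", 100, "A", "T")
    assert not match(d, s, OVERLAP_INDEL)


def test_insertion_anchor_overlap():
    # insertion span covers its two flanking anchors: an insertion at the
    # edge of a deletion's span overlaps it
    ins = _nv("1", 104, "A", "ATT")
    dele = _nv("1", 100, "ATTTG", "A")  # span [99, 104)
    assert ins.span.start < dele.span.end
    assert match(ins, dele, OVERLAP_INDEL)


@given(st.data())
def test_match_flags_equals_all_pairs_brute_force(data):
    rng = data.draw(st.randoms(use_true_random=False))
    def rand_set(n):
        out = []
        for _ in range(n):
            pos = rng.randrange(1, 60)
            kind = rng.random()
            if kind < 0.5:
                out.append(_nv("1", pos, "A", rng.choice("CGT")))
            elif kind < 0.75:
                out.append(_nv("1", pos, "A" + "T" * rng.randrange(1, 4), "A"))
            else:
                out.append(_nv("1", pos, "A", "A" + "C" * rng.randrange(1, 4)))
        return out
    avars, bvars = rand_set(rng.randrange(0, 40)), rand_set(rng.randrange(0, 40))
    for mode in (EXACT, OVERLAP_INDEL):
        fa, fb = match_flags(avars, bvars, mode)
        assert fa == [any(match(a, b, mode) for b in bvars) for a in avars]
        assert fb == [any(match(b, a, mode) for a in avars) for b in bvars]
        # symmetry and reflexivity of the pairwise relation
        for a in avars[:10]:
            assert match(a, a, mode)
            for b in bvars[:10]:
                assert match(a, b, mode) == match(b, a, mode)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def test_pad_regions_examples():
    r = TargetRegions([GenomicInterval("1", 1000, 2000)])
    p = pad_regions(r, 1000)
    assert p.intervals == (GenomicInterval("1", 0, 3000),)
    assert p.padded and p.pad_bp == 1000

    # two targets whose padded extents overlap merge into one interval
    r2 = TargetRegions([GenomicInterval("1", 100, 200),
                        GenomicInterval("1", 2100, 2400)])
    p2 = pad_regions(r2, 1000)
    assert p2.intervals == (GenomicInterval("1", 0, 3400),)

    assert pad_regions(r2, 0).intervals == r2.intervals


@given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 300)),
                min_size=1, max_size=20),
       st.integers(0, 500))
def test_pad_monotone_and_merged(ivs, pad):
    regions = TargetRegions(
        [GenomicInterval("1", s, s + ln) for s, ln in ivs])
    padded = regions.pad(pad)
    # merged representation: sorted, disjoint, non-abutting
    for prev, cur in zip(padded.intervals, padded.intervals[1:]):
        assert prev.end < cur.start
    # every base covered before is covered after; total length grows
    for iv in regions:
        assert padded.overlaps(iv.chrom, iv.start, iv.end)
        for probe in (iv.start, iv.end - 1):
            assert padded.overlaps(iv.chrom, probe, probe + 1)
    assert padded.total_length() >= regions.total_length()


def test_in_regions_partial_overlap():
    regions = TargetRegions([GenomicInterval("1", 100, 200)])
    assert in_regions(_nv("1", 151, "A", "G"), regions)  # SNV at base 150
    # deletion spanning 95..105 (0-based): breakpoint outside, overlap inside
    boundary_del = _nv("1", 96, "ACGTACGTAC", "A")
    assert boundary_del.span.start < 100 < boundary_del.span.end
    assert in_regions(boundary_del, regions)
    assert not in_regions(_nv("1", 251, "A", "G"), regions)


def test_in_regions_grows_with_padding(small_cohort):
    regions = small_cohort.targets
    padded = regions.pad(1000)
    sid = small_cohort.sample_ids[0]
    for av in small_cohort.annotated_b[sid]:
        if in_regions(av.variant, regions):
            assert in_regions(av.variant, padded)


def test_bed_round_trip(tmp_path):
    r = TargetRegions([GenomicInterval("1", 10, 20),
                       GenomicInterval("2", 5, 9)])
    path = tmp_path / "t.bed"
    r.to_bed(path)
    assert TargetRegions.from_bed(path) == r


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("1", -1, 10)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
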