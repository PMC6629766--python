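"""Full-length cDNA pileup, Fisher-based SNP calling with homopolymer
suppression, and the full-length read-support genotype rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locuskit.cdnasnps import (
    call_snps,
    fisher_p_enrichment,
    flnc_pileup,
    genotype_sample,
    link_snps_to_isoforms,
    unlinkable_pairs,
)
from locuskit.models import AlignedRead, Interval, Isoform, SnpCallerParams
from locuskit.sequence import encode


def brute_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exact hypergeometric tail summation for the
    one-sided Fisher test on [[a, b], [c, d]]."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    hi = min(r1, c1)

    def pt(x: int) -> float:
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

    return sum(pt(x) for x in range(a, hi + 1))


class _NullModel:
    """Bare reference for caller tests on constructed pileups."""

    def __init__(self, ref_seq):
        self.contig_name = "null"
        self.ref_seq = ref_seq


def _mk_read(rid, start, seq, quals, sample="S"):
    return AlignedRead(read_id=rid, contig="c", start=start, strand="+",
                       sample_id=sample, cigar=[("M", len(seq))], query=seq,
                       quals=quals)


# --- pileup ----------------------------------------------------------------


def test_pileup_counts_and_qv_filter():
    reads = [_mk_read(f"a{i}", 1, "ACGT", [30] * 4) for i in range(50)]
    reads += [_mk_read(f"b{i}", 1, "TCGT", [5, 30, 30, 30]) for i in range(10)]
    pooled, per_sample = flnc_pileup(reads, 4, SnpCallerParams())
    assert pooled[0, 0] == 50  # A at QV 30
    assert pooled[0, 3] == 0  # alt T bases at QV 5 are excluded
    assert pooled[1, 1] == 60
    assert set(per_sample) == {"S"}


def test_pileup_restricted_to_assigned_reads():
    reads = [_mk_read("keep", 1, "ACGT", [30] * 4), _mk_read("drop", 1, "ACGT", [30] * 4)]
    pooled, _ = flnc_pileup(reads, 4, SnpCallerParams(), assigned_read_ids={"keep"})
    assert pooled[0, 0] == 1


# --- calling ---------------------------------------------------------------


def _pileup_single(ref, pos0, alt_base, alt_n, cov):
    L = len(ref)
    pooled = np.zeros((L, 4), dtype=np.int64)
    codes = encode(ref)
    for i in range(L):
        pooled[i, codes[i]] = cov
    pooled[pos0, codes[pos0]] = cov - alt_n
    pooled[pos0, "ACGT".index(alt_base)] = alt_n
    return pooled


def test_below_coverage_positions_not_tested():
    ref = "ACGTACGTAC"
    pooled = _pileup_single(ref, 4, "T", 20, 39)  # coverage 39 < 40
    snps, m = call_snps(pooled, {"S": pooled}, _NullModel(ref), SnpCallerParams())
    assert m == 0 and snps == []


def test_no_alt_not_called():
    ref = "ACGTACGTAC"
    pooled = _pileup_single(ref, 4, "T", 0, 100)
    snps, m = call_snps(pooled, {"S": pooled}, _NullModel(ref), SnpCallerParams())
    assert m == 10 and snps == []


def test_strong_alt_called_with_exact_oracle_p():
    """cov 100, alt 30, error 0.005, m = 1: the caller's p equals the
    brute-force hypergeometric tail on [[30, 70], [1, 99]]."""
    ref = "ACGTACGTAC" * 4  # keep m small but the site testable
    pooled = _pileup_single(ref, 4, "T", 30, 100)
    # only position 4 gets coverage >= 40
    mask = np.ones(len(ref), dtype=bool)
    mask[4] = False
    pooled[mask] = 0
    snps, m = call_snps(pooled, {"S": pooled}, _NullModel(ref), SnpCallerParams())
    assert m == 1
    assert len(snps) == 1
    want = brute_fisher_greater(30, 70, 1, 99)
    assert snps[0].raw_p == pytest.approx(want, abs=1e-12)
    assert snps[0].alt_base == "T"


def test_homopolymer_adjacent_site_suppressed():
    ref = "CGCGAAAATCGCGCGCG"
    pos0 = 8  # the T immediately 3' of the AAAA run
    pooled = _pileup_single(ref, pos0, "G", 50, 100)
    snps, m = call_snps(pooled, {"S": pooled}, _NullModel(ref), SnpCallerParams())
    assert m == len(ref)
    assert snps == []  # would be significant, but the homopolymer gate holds
    # same signal away from the run is called
    ref2 = "CGCGCATGTCGCGCGCG"
    pooled2 = _pileup_single(ref2, 8, "G", 50, 100)
    snps2, _ = call_snps(pooled2, {"S": pooled2}, _NullModel(ref2), SnpCallerParams())
    assert [s.pos for s in snps2] == [9]


def test_fisher_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(99)
    for _ in range(300):
        cov = int(rng.integers(40, 501))
        alt = int(rng.integers(0, cov + 1))
        err = float(rng.choice([0.001, 0.005, 0.02]))
        e = math.floor(err * cov + 0.5)
        assert fisher_p_enrichment(alt, cov - alt, err) == pytest.approx(
            brute_fisher_greater(alt, cov - alt, e, cov - e), abs=1e-12
        )


# --- genotype rule ---------------------------------------------------------


@pytest.mark.parametrize(
    "ref_n,alt_n,expected",
    [(6, 6, "het"), (5, 5, "het"), (5, 4, "homo_ref"), (4, 5, "homo_alt"),
     (4, 4, "inconclusive"), (0, 0, "inconclusive"), (100, 4, "homo_ref")],
)
def test_genotype_rule_examples(ref_n, alt_n, expected):
    assert genotype_sample(ref_n, alt_n) == expected


@settings(max_examples=200, derandomize=True)
@given(st.integers(0, 500), st.integers(0, 500))
def test_genotype_rule_total_function(ref_n, alt_n):
    out = genotype_sample(ref_n, alt_n)
    assert out in {"het", "homo_ref", "homo_alt", "inconclusive"}
    # the quoted rule, restated independently
    if ref_n >= 5 and alt_n >= 5:
        assert out == "het"
    elif ref_n >= 5 or alt_n >= 5:
        assert out == ("homo_ref" if ref_n >= 5 else "homo_alt")
    else:
        assert out == "inconclusive"


# --- isoform linkage -------------------------------------------------------


def test_snp_isoform_coverage_by_exon_structure():
    from locuskit.models import CdnaSnp

    iso_short = Isoform("short_utr", "c", "-", [Interval(2000, 2600), Interval(5000, 5400)])
    iso_long = Isoform("long_utr", "c", "-", [Interval(800, 2600), Interval(5000, 5400)])
    snp_utr = CdnaSnp("c", 1200, "G", "A", 1e-9, 10, True, 50, 50)
    snp_shared = CdnaSnp("c", 5100, "C", "T", 1e-9, 10, True, 50, 50)
    link_snps_to_isoforms([snp_utr, snp_shared], [iso_short, iso_long])
    assert snp_utr.covering_isoforms == ["long_utr"]
    assert set(snp_shared.covering_isoforms) == {"short_utr", "long_utr"}


def test_unlinkable_pairs_disjoint_isoform_sets():
    from locuskit.models import CdnaSnp

    iso_a = Isoform("a", "c", "-", [Interval(100, 200)])
    iso_b = Isoform("b", "c", "-", [Interval(300, 400)])
    s1 = CdnaSnp("c", 150, "G", "A", 1e-9, 10, True, 5, 5)
    s2 = CdnaSnp("c", 350, "G", "A", 1e-9, 10, True, 5, 5)
    link_snps_to_isoforms([s1, s2], [iso_a, iso_b])
    assert unlinkable_pairs([s1, s2]) == [(150, 350)]
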