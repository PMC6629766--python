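"""Spanning-subsequence extraction, size/similarity clustering, star
consensus, repeat-unit counting and diploid repeat genotyping."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locuskit.models import AlignedRead, Interval, RegionSubsequence
from locuskit.strhap import (
    cluster_by_size_and_similarity,
    cluster_consensus,
    count_repeat_units,
    extract_spanning,
    genotype_region,
    genotype_samples,
)
from locuskit.truth import CT_GENOTYPES, TTG_GENOTYPES


def _sub(seq, rid="r", sample="S"):
    return RegionSubsequence(read_id=rid, sample_id=sample, sequence=seq)


# --- extraction ------------------------------------------------------------


def test_errorfree_spanning_read_yields_reference_slice(model):
    region = model.str_region
    lo, hi = region.start - 100, region.end + 100
    seg = model.ref_seq[lo - 1 : hi]
    read = AlignedRead(read_id="r", contig=model.contig_name, start=lo, strand="+",
                       sample_id="S", cigar=[("M", len(seg))], query=seg,
                       quals=[40] * len(seg))
    subs = extract_spanning([read], region)
    assert len(subs) == 1
    assert subs[0].sequence == model.slice(region)


def test_read_ending_inside_region_excluded(model):
    region = model.str_region
    lo = region.start - 100
    end = region.start + 10  # stops inside
    seg = model.ref_seq[lo - 1 : end]
    read = AlignedRead(read_id="r", contig=model.contig_name, start=lo, strand="+",
                       sample_id="S", cigar=[("M", len(seg))], query=seg,
                       quals=[40] * len(seg))
    assert extract_spanning([read], region) == []


def test_contracted_allele_extracted_with_deletion(model):
    """A (TTG)9 haplotype reduces extracted length by exactly 3 x 7."""
    region = model.str_region
    lo, hi = region.start - 50, region.end + 50
    left = model.ref_seq[lo - 1 : region.start - 1]
    right = model.ref_seq[region.end : hi]
    allele = model.str_unit * 9
    query = left + allele + right
    cigar = [("M", len(left) + len(allele)), ("D", 21), ("M", len(right))]
    read = AlignedRead(read_id="r", contig=model.contig_name, start=lo, strand="+",
                       sample_id="S", cigar=cigar, query=query, quals=[40] * len(query))
    subs = extract_spanning([read], region)
    assert len(subs) == 1
    assert subs[0].sequence == allele
    assert len(subs[0].sequence) == region.length - 21


# --- clustering ------------------------------------------------------------


def test_two_length_groups_two_clusters():
    a = [_sub("ACGT" * 10, rid=f"a{i}") for i in range(10)]
    b = [_sub("ACGT" * 10 + "ACGTACGTA", rid=f"b{i}") for i in range(10)]  # +9 bases
    clusters = cluster_by_size_and_similarity(a + b)
    assert len(clusters) == 2
    assert sorted(len(c) for c in clusters) == [10, 10]


def test_identical_sequences_single_cluster():
    clusters = cluster_by_size_and_similarity([_sub("ACGTACGT", rid=f"r{i}") for i in range(10)])
    assert len(clusters) == 1


def test_small_clusters_discarded():
    subs = [_sub("ACGT" * 10, rid=f"a{i}") for i in range(5)] + [_sub("TTTT" * 30, rid="odd")]
    clusters = cluster_by_size_and_similarity(subs, min_cluster_support=3)
    assert len(clusters) == 1 and len(clusters[0]) == 5


# --- consensus -------------------------------------------------------------


def test_consensus_of_identical_members():
    assert cluster_consensus([_sub("GATTACA") for _ in range(5)]) == "GATTACA"


def test_consensus_majority_overrides_single_substitution():
    s = "ACGTACGTACGTACGT"
    mutated = s[:5] + "T" + s[6:]
    members = [_sub(s, rid=f"r{i}") for i in range(9)] + [_sub(mutated, rid="m")]
    assert cluster_consensus(members) == s


def test_consensus_majority_overrides_indel_noise():
    s = "ACGTTGCATTGGCATGCAAT"
    with_del = s[:7] + s[8:]
    with_ins = s[:12] + "A" + s[12:]
    members = [_sub(s, rid=f"r{i}") for i in range(6)] + [_sub(with_del, rid="d"),
                                                          _sub(with_ins, rid="i")]
    assert cluster_consensus(members) == s


# --- unit counting ---------------------------------------------------------


@pytest.mark.parametrize(
    "seq,unit,expected",
    [
        ("AA" + "TTG" * 12 + "CC", "TTG", 12),
        ("TTG" * 16, "TTG", 16),
        ("TTGTTGATTGTTG", "TTG", 2),
        ("", "TTG", 0),
        ("TTGT", "TTG", 1),
    ],
)
def test_count_repeat_units_examples(seq, unit, expected):
    assert count_repeat_units(seq, unit) == expected


def test_count_repeat_units_empty_unit_raises():
    with pytest.raises(ValueError):
        count_repeat_units("ACGT", "")


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=60),
       st.text(alphabet="ACGT", min_size=1, max_size=4))
def test_count_repeat_units_matches_regex_oracle(seq, unit):
    runs = [len(m.group(0)) // len(unit)
            for m in re.finditer(f"(?:{re.escape(unit)})+", seq)]
    assert count_repeat_units(seq, unit) == (max(runs) if runs else 0)


# --- genotyping ------------------------------------------------------------


def test_het_genotype_string_and_ordering():
    a15 = [_sub("TTG" * 15, rid=f"a{i}") for i in range(6)]
    a12 = [_sub("TTG" * 12, rid=f"b{i}") for i in range(5)]
    gt = genotype_region([a12, a15], "N-1", "ttg", unit="TTG")
    assert gt.unit_string("TTG") == "(TTG)15/(TTG)12"
    assert (gt.support1, gt.support2) == (6, 5)


def test_hom_genotype_from_single_cluster():
    gt = genotype_region([[_sub("TTG" * 12, rid=f"r{i}") for i in range(8)]],
                         "DLB-1", "ttg", unit="TTG")
    assert gt.unit_string("TTG") == "(TTG)12/(TTG)12"


def test_zero_clusters_unresolved():
    gt = genotype_region([], "S", "ttg", unit="TTG")
    assert gt.flag == "unresolved"
    assert gt.unit_string("TTG") == "unresolved"


def test_more_than_two_clusters_flagged():
    cl = [[_sub("TTG" * n, rid=f"{n}_{i}") for i in range(sup)]
          for n, sup in ((15, 8), (12, 6), (9, 3))]
    gt = genotype_region(cl, "S", "ttg", unit="TTG")
    assert gt.flag == "extra_clusters"
    assert (gt.unit_count1, gt.unit_count2) == (15, 12)


def test_end_to_end_repeat_recovery_on_simulation(gdna_two_samples):
    """Planted TTG and CT-rich genotypes recovered exactly for the
    simulated samples."""
    model, truths, reads, _ = gdna_two_samples
    ttg = genotype_samples(reads, model.str_region, "ttg", unit=model.str_unit)
    ct = genotype_samples(reads, model.ct_rich_region, "ct",
                          catalog=model.ct_haplotype_catalog)
    for t in truths:
        g = ttg[t.sample_id]
        assert (g.unit_count1, g.unit_count2) == (
            max(TTG_GENOTYPES[t.sample_id]), min(TTG_GENOTYPES[t.sample_id]))
        assert min(g.support1, g.support2) >= 5
        c = ct[t.sample_id]
        assert sorted((int(c.label1), int(c.label2))) == sorted(CT_GENOTYPES[t.sample_id])
        # consensus is the exact catalogue sequence
        want = {model.ct_haplotype_catalog[h] for h in CT_GENOTYPES[t.sample_id]}
        assert {c.allele1, c.allele2} == want
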