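"""Pileup genotyping, the phase-consistency filter, read-backed phasing
and phase-block statistics."""

import numpy as np
import pytest

from locuskit.models import AlignedRead, Interval, PhaseBlock
from locuskit.variants import (
    default_masks,
    phase_consistency_filter,
    phasing_summary,
    pileup_genotype,
    read_backed_phase,
)

from conftest import switch_errors


def _reads_at(model, pos, n_ref, n_alt, alt_base, sample="S1", width=200, qv=40):
    """n_ref reference reads and n_alt alt-carrying reads over [pos-w, pos+w]."""
    lo = pos - width
    seg = model.ref_seq[lo - 1 : pos + width]
    reads = []
    for i in range(n_ref + n_alt):
        q = list(seg)
        if i >= n_ref:
            q[pos - lo] = alt_base
        reads.append(
            AlignedRead(
                read_id=f"r{i:03d}", contig=model.contig_name, start=lo, strand="+",
                sample_id=sample, cigar=[("M", len(seg))], query="".join(q),
                quals=[qv] * len(seg),
            )
        )
    return reads


def _clean_pos(model, anchor=20_000):
    masks = default_masks(model)
    pos = anchor
    while any(m.contains(pos) for m in masks):
        pos += 1000
    return pos


@pytest.mark.parametrize(
    "n_ref,n_alt,expected",
    [(30, 0, None), (15, 15, "0/1"), (2, 28, "1/1"), (25, 3, "0/0")],
)
def test_genotype_fraction_thresholds(model, n_ref, n_alt, expected):
    pos = _clean_pos(model)
    ref_base = model.ref_seq[pos - 1]
    alt_base = "A" if ref_base != "A" else "C"
    reads = _reads_at(model, pos, n_ref, n_alt, alt_base)
    calls = pileup_genotype(reads, model)
    at_site = [c for c in calls if c.pos == pos]
    if expected is None or expected == "0/0":
        assert at_site == []  # no sample reaches the het threshold
    else:
        assert len(at_site) == 1
        assert at_site[0].genotypes["S1"] == expected


def test_low_qv_bases_excluded_from_fractions(model):
    pos = _clean_pos(model)
    ref_base = model.ref_seq[pos - 1]
    alt_base = "A" if ref_base != "A" else "C"
    good = _reads_at(model, pos, 20, 0, alt_base, qv=40)
    noisy = _reads_at(model, pos, 0, 12, alt_base, qv=5)
    for i, r in enumerate(noisy):
        r.read_id = f"n{i:03d}"
    calls = pileup_genotype(good + noisy, model)
    assert [c for c in calls if c.pos == pos] == []


def test_wrong_contig_raises(model):
    r = AlignedRead(read_id="x", contig="other", start=1, strand="+", sample_id="S",
                    cigar=[("M", 5)], query="ACGTA", quals=[40] * 5)
    with pytest.raises(ValueError, match="other"):
        pileup_genotype([r], model)


def test_simulated_substitution_concordance(gdna_two_samples):
    """Planted substitutions at per-sample depth >= 20 genotype at >= 99%
    concordance with zero extra het/hom calls."""
    model, truths, reads, _ = gdna_two_samples
    calls = pileup_genotype(reads, model)
    masks = default_masks(model)
    called = {(c.pos, c.ref_allele, c.alt_allele): c for c in calls if c.is_snp}
    for t in truths:
        sid = t.sample_id
        planted = {}
        for h in (0, 1):
            for v in t.haplotypes[h]:
                if v.is_snp:
                    planted[(v.pos, v.ref, v.alt)] = planted.get((v.pos, v.ref, v.alt), 0) + 1
        total = concordant = 0
        for key, copies in planted.items():
            if any(m.contains(key[0]) for m in masks):
                continue
            c = called.get(key)
            if c is None or c.depths.get(sid, 0) < 20:
                continue
            total += 1
            want = {1: "0/1", 2: "1/1"}[copies]
            if c.genotypes[sid] == want:
                concordant += 1
        assert total > 50
        assert concordant / total >= 0.99
        # no spurious non-ref genotypes at unplanted positions
        for key, c in called.items():
            if any(m.contains(key[0]) for m in masks):
                continue
            if key not in planted and c.depths.get(sid, 0) >= 20:
                assert c.genotypes[sid] == "0/0", key


def test_simulated_indels_detected(gdna_two_samples):
    model, truths, reads, _ = gdna_two_samples
    calls = pileup_genotype(reads, model)
    indel_calls = {(c.pos, c.ref_allele, c.alt_allele) for c in calls if not c.is_snp}
    t = truths[0]
    planted = {(v.pos, v.ref, v.alt) for h in (0, 1) for v in t.haplotypes[h]
               if not v.is_snp and len(v.ref) < 40}
    masks = default_masks(model)
    planted = {k for k in planted if not any(m.contains(k[0]) for m in masks)}
    found = planted & indel_calls
    assert len(found) / len(planted) >= 0.9


# ---------------------------------------------------------------------------
# phase consistency


def _pair_reads(model, pos_a, pos_b, configs, sample="S1"):
    """Reads covering pos_a..pos_b carrying the given (allele_a, allele_b)
    configurations; allele 1 plants a fixed alt base."""
    lo, hi = pos_a - 20, pos_b + 20
    seg = model.ref_seq[lo - 1 : hi]

    def alt(pos):
        return "A" if model.ref_seq[pos - 1] != "A" else "C"

    reads = []
    for i, (aa, ab) in enumerate(configs):
        q = list(seg)
        if aa:
            q[pos_a - lo] = alt(pos_a)
        if ab:
            q[pos_b - lo] = alt(pos_b)
        reads.append(
            AlignedRead(read_id=f"p{i:03d}", contig=model.contig_name, start=lo,
                        strand="+", sample_id=sample, cigar=[("M", len(seg))],
                        query="".join(q), quals=[40] * len(seg))
        )
    return reads


def test_consistent_het_pair_passes_filter(model):
    pos_a = _clean_pos(model)
    pos_b = pos_a + 300
    reads = _pair_reads(model, pos_a, pos_b, [(0, 0)] * 5 + [(1, 1)] * 5)
    calls = pileup_genotype(reads, model)
    phase_consistency_filter(calls, reads, "S1")
    assert all(c.qual_flags["S1"] == "pass" for c in calls)


def test_random_cooccurrence_artifact_flagged(model):
    """A site whose alleles co-occur 50/50 with every nearby het is a
    sequencing artifact and is flagged; its real partners are kept."""
    pos_a = _clean_pos(model)
    pos_b = pos_a + 200  # real het, consistent with pos_c
    pos_c = pos_a + 400  # real het
    lo = pos_a - 20
    hi = pos_c + 20
    seg = model.ref_seq[lo - 1 : hi]

    def alt(pos):
        return "A" if model.ref_seq[pos - 1] != "A" else "C"

    reads = []
    rng = np.random.default_rng(0)
    for i in range(24):
        hap = i % 2
        art = i % 4 < 2  # artifact allele independent of haplotype
        q = list(seg)
        if hap:
            q[pos_b - lo] = alt(pos_b)
            q[pos_c - lo] = alt(pos_c)
        if art:
            q[pos_a - lo] = alt(pos_a)
        reads.append(
            AlignedRead(read_id=f"a{i:03d}", contig=model.contig_name, start=lo,
                        strand="+", sample_id="S1", cigar=[("M", len(seg))],
                        query="".join(q), quals=[40] * len(seg))
        )
    calls = pileup_genotype(reads, model)
    assert {c.pos for c in calls} == {pos_a, pos_b, pos_c}
    phase_consistency_filter(calls, reads, "S1")
    flags = {c.pos: c.qual_flags["S1"] for c in calls}
    assert flags[pos_a] == "phase_inconsistent"
    assert flags[pos_b] == "pass" and flags[pos_c] == "pass"


def test_isolated_het_left_unflagged(model):
    pos = _clean_pos(model)
    ref_base = model.ref_seq[pos - 1]
    alt_base = "A" if ref_base != "A" else "C"
    reads = _reads_at(model, pos, 10, 10, alt_base)
    calls = pileup_genotype(reads, model)
    phase_consistency_filter(calls, reads, "S1")
    assert [c.qual_flags["S1"] for c in calls if c.pos == pos] == ["pass"]


# ---------------------------------------------------------------------------
# phasing


def test_three_linked_sites_one_block(model):
    pos_a = _clean_pos(model)
    pos_b, pos_c = pos_a + 200, pos_a + 400
    lo = pos_a - 20
    seg = model.ref_seq[lo - 1 : pos_c + 20]

    def alt(pos):
        return "A" if model.ref_seq[pos - 1] != "A" else "C"

    reads = []
    for i in range(10):
        hap = i % 2
        q = list(seg)
        if hap:
            for p in (pos_a, pos_b, pos_c):
                q[p - lo] = alt(p)
        reads.append(
            AlignedRead(read_id=f"r{i:03d}", contig=model.contig_name, start=lo,
                        strand="+", sample_id="S1", cigar=[("M", len(seg))],
                        query="".join(q), quals=[40] * len(seg))
        )
    calls = pileup_genotype(reads, model)
    phase_consistency_filter(calls, reads, "S1")
    blocks = read_backed_phase(calls, reads, "S1", model.contig_name)
    assert len(blocks) == 1
    assert blocks[0].n_sites == 3
    assert blocks[0].start == pos_a and blocks[0].end == pos_c


def test_unlinked_clusters_make_separate_blocks(model):
    pos_a = _clean_pos(model)
    far = _clean_pos(model, anchor=pos_a + 30_000)
    reads = (
        _pair_reads(model, pos_a, pos_a + 200, [(0, 0)] * 5 + [(1, 1)] * 5)
        + [r for r in _pair_reads(model, far, far + 200, [(0, 0)] * 5 + [(1, 1)] * 5)]
    )
    for i, r in enumerate(reads):
        r.read_id = f"u{i:03d}"
    calls = pileup_genotype(reads, model)
    phase_consistency_filter(calls, reads, "S1")
    blocks = read_backed_phase(calls, reads, "S1", model.contig_name)
    assert len(blocks) == 2


def test_simulated_phasing_zero_switch_errors(gdna_two_samples):
    model, truths, reads, _ = gdna_two_samples
    calls = pileup_genotype(reads, model)
    for t in truths:
        sid = t.sample_id
        phase_consistency_filter(calls, reads, sid)
        blocks = read_backed_phase(calls, reads, sid, model.contig_name)
        assert blocks
        assert sum(switch_errors(b, t) for b in blocks) == 0


def test_phasing_summary_arithmetic():
    blocks = [
        PhaseBlock("S", "c", 1, 10_000, [(1, "0|1"), (10_000, "1|0")]),
        PhaseBlock("S", "c", 20_001, 30_000, [(20_001, "0|1"), (30_000, "0|1")]),
    ]
    s = phasing_summary(blocks, Interval(1, 100_000), "S")
    assert s.total_phased_span == 20_000
    assert s.fraction_of_region == pytest.approx(0.20)
    assert s.longest_block == 10_000


def test_phasing_summary_no_blocks():
    s = phasing_summary([], Interval(1, 1000), "S")
    assert s.fraction_of_region == 0.0 and s.longest_block == 0


def test_summary_equals_bruteforce_union(gdna_two_samples):
    """Summed block spans must equal the brute-force union of block
    intervals (blocks never overlap)."""
    model, truths, reads, _ = gdna_two_samples
    calls = pileup_genotype(reads, model)
    sid = truths[0].sample_id
    phase_consistency_filter(calls, reads, sid)
    blocks = read_backed_phase(calls, reads, sid, model.contig_name)
    s = phasing_summary(blocks, Interval(1, model.length), sid)
    covered = np.zeros(model.length + 1, dtype=bool)
    for b in blocks:
        covered[b.start : b.end + 1] = True
    assert s.total_phased_span == int(covered.sum())
    assert s.fraction_of_region >= 0.5
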