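"""Isoform collapse, canonical-splice/FL filtering, splice-pattern
classification, abundance tables, junction validation and ORF calls."""

import numpy as np
import pytest

from locuskit.isoforms import (
    abundance,
    annotated_junctions,
    classify_splice_pattern,
    collapse_flnc,
    filter_isoforms,
    junction_motif,
    predict_orf,
    validate_junctions,
)
from locuskit.locus import TRUE_CLASSES, VALID_ISOFORMS, isoform_chains
from locuskit.models import AlignedRead, Interval, Isoform


def _fl_read(model, chain, rid, sample="S", jitter=(0, 0)):
    exons = [Interval(c.start, c.end) for c in chain]
    exons[0] = Interval(exons[0].start + jitter[0], exons[0].end)
    exons[-1] = Interval(exons[-1].start, exons[-1].end - jitter[1])
    cigar = []
    parts = []
    prev = None
    for e in exons:
        if prev is not None:
            cigar.append(("N", e.start - prev - 1))
        cigar.append(("M", e.length))
        parts.append(model.ref_seq[e.start - 1 : e.end])
        prev = e.end
    q = "".join(parts)
    return AlignedRead(read_id=rid, contig=model.contig_name, start=exons[0].start,
                       strand="-", sample_id=sample, cigar=cigar, query=q,
                       quals=[40] * len(q))


def test_identical_reads_collapse_to_single_isoform(model):
    chain = isoform_chains(model.gene)["iso_E1_u300"]
    reads = [_fl_read(model, chain, f"r{i:02d}", jitter=(i % 4, i % 3))
             for i in range(30)]
    isos = collapse_flnc(reads, model.contig_name, "-")
    assert len(isos) == 1
    assert isos[0].total_fl == 30


def test_distant_utr_ends_stay_separate(model):
    c300 = isoform_chains(model.gene)["iso_E1_u300"]
    c2600 = isoform_chains(model.gene)["iso_E1_u2600"]
    reads = [_fl_read(model, c300, f"a{i}") for i in range(10)]
    reads += [_fl_read(model, c2600, f"b{i}") for i in range(10)]
    isos = collapse_flnc(reads, model.contig_name, "-")
    assert len(isos) == 2


def test_collapse_invariant_under_read_permutation(model):
    chains = isoform_chains(model.gene)
    reads = []
    for k, name in enumerate(VALID_ISOFORMS[:5]):
        reads += [_fl_read(model, chains[name], f"{name}_{i}", jitter=(i % 5, i % 7))
                  for i in range(8)]
    rng = np.random.default_rng(2)
    shuffled = list(reads)
    rng.shuffle(shuffled)

    def key(isos):
        return sorted(
            (tuple(tuple(j) for j in iso.junctions), iso.exon_chain[0].start,
             iso.exon_chain[-1].end, iso.total_fl)
            for iso in isos
        )

    a = collapse_flnc(reads, model.contig_name, "-")
    b = collapse_flnc(shuffled, model.contig_name, "-")
    assert key(a) == key(b)


def test_filter_boundaries_and_reasons(model):
    chains = isoform_chains(model.gene)
    ok = [_fl_read(model, chains["iso_E1_u300"], f"a{i}") for i in range(20)]
    low = [_fl_read(model, chains["iso_E1_u2600"], f"b{i}") for i in range(19)]
    bad = [_fl_read(model, chains["iso_decoy_noncanonical"], f"c{i}") for i in range(25)]
    isos = collapse_flnc(ok + low + bad, model.contig_name, "-")
    retained, dropped = filter_isoforms(isos, model, min_fl=20)
    assert len(retained) == 1 and retained[0].total_fl == 20
    reasons = {d.isoform.total_fl: d.reason for d in dropped}
    assert reasons[19].startswith("low_fl")
    assert reasons[25].startswith("noncanonical:AT-AG")


def test_retained_junction_motifs_verified_against_reference(model, flnc_cohort):
    _, _, reads, _ = flnc_cohort
    isos = collapse_flnc(reads, model.contig_name, "-")
    retained, _ = filter_isoforms(isos, model)
    assert retained
    for iso in retained:
        for j in iso.junctions:
            assert junction_motif(model.ref_seq, j, "-") in {"GT-AG", "GC-AG"}


def test_splice_classification_of_planted_repertoire(model):
    chains = isoform_chains(model.gene)
    for name in VALID_ISOFORMS:
        iso = Isoform(isoform_id=name, contig=model.contig_name, strand="-",
                      exon_chain=list(chains[name]))
        assert classify_splice_pattern(iso, model.gene) == TRUE_CLASSES[name], name


def test_abundance_percentages(model):
    isos = [
        Isoform("i1", "c", "-", [Interval(1, 10)], fl_counts={"S1": 50, "S2": 10}),
        Isoform("i2", "c", "-", [Interval(1, 10)], fl_counts={"S1": 50, "S2": 30}),
    ]
    df = abundance(isos)
    assert df.loc["i1", "S1"] == pytest.approx(50.0)
    assert df.loc["i1", "S2"] == pytest.approx(25.0)
    assert df.sum(axis=0)["S1"] == pytest.approx(100.0)


def test_class_abundance_columns_sum_to_100(model, flnc_cohort):
    _, _, reads, _ = flnc_cohort
    isos = collapse_flnc(reads, model.contig_name, "-")
    retained, _ = filter_isoforms(isos, model)
    for iso in retained:
        iso.splice_class = classify_splice_pattern(iso, model.gene)
    df = abundance(retained, by_class=True)
    assert df.shape[1] == 12
    for col in df:
        assert df[col].sum() == pytest.approx(100.0, abs=0.01)


@pytest.mark.parametrize("count,status", [(10, "supported"), (9, "unsupported"),
                                          (0, "unsupported")])
def test_junction_support_boundary(model, count, status):
    chain = isoform_chains(model.gene)["iso_novelstart_u1000"]
    iso = Isoform("x", model.contig_name, "-", list(chain))
    novel = [j for j in iso.junctions if j not in annotated_junctions(model.gene)]
    assert novel
    table = {(model.contig_name, j[0], j[1]): count for j in iso.junctions}
    df = validate_junctions([iso], model.gene, table)
    novel_rows = df[df["novel"]]
    assert set(novel_rows["status"]) == {status}
    assert bool(novel_rows["isoform_confirmed"].iloc[0]) == (status == "supported")


def test_junction_validation_without_table_unknown(model):
    chain = isoform_chains(model.gene)["iso_E1_u300"]
    iso = Isoform("x", model.contig_name, "-", list(chain))
    df = validate_junctions([iso], model.gene, None)
    assert set(df["status"]) == {"unknown"}


def test_annotated_junctions_cover_canonical_chain(model):
    known = annotated_junctions(model.gene)
    chain = isoform_chains(model.gene)["iso_E1_u300"]
    for j in ((a.end + 1, b.start - 1) for a, b in zip(chain, chain[1:])):
        assert j in known


@pytest.mark.parametrize(
    "name,status,length",
    [
        ("iso_E1_u300", "canonical", 141),
        ("iso_E1_u2600", "canonical", 141),
        ("iso_skip3_u300", "frame_maintained_shorter", 99),
        ("iso_skip5_u300", "frame_maintained_shorter", 113),
        ("iso_novelend", "truncated", None),
    ],
)
def test_orf_prediction_statuses(model, name, status, length):
    chain = isoform_chains(model.gene)[name]
    iso = Isoform(name, model.contig_name, "-", list(chain))
    got_status, got_len = predict_orf(iso, model.gene, model.ref_seq)
    assert got_status == status
    if length is not None:
        assert got_len == length


def test_orf_none_without_start_codon(model):
    # a transcript made of pure pyrimidine sequence has no ATG
    iso = Isoform("x", model.contig_name, "-",
                  [Interval(model.ct_rich_region.start, model.ct_rich_region.end)])
    status, plen = predict_orf(iso, model.gene, model.ref_seq)
    assert status == "none" and plen is None
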