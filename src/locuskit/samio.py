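"""SAM / VCF interchange via pysam.

Internal coordinates are 1-based inclusive; pysam uses 0-based — the
conversion happens only here.
"""

from __future__ import annotations

import pysam

from .models import AlignedRead, LocusModel, PhaseBlock, VariantCall

_OPS = {"M": 0, "I": 1, "D": 2, "N": 3}
_OPS_REV = {v: k for k, v in _OPS.items()}


def sam_header(locus: LocusModel, sample_ids: list[str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": locus.contig_name, "LN": locus.length}],
            "RG": [{"ID": s, "SM": s} for s in sample_ids],
            "PG": [{"ID": "locuskit", "PN": "locuskit"}],
        }
    )


def to_segment(read: AlignedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = read.read_id
    a.reference_id = 0
    a.reference_start = read.start - 1
    a.mapping_quality = 60
    a.flag = (16 if read.strand == "-" else 0) | (0x400 if read.is_duplicate else 0)
    a.cigartuples = [(_OPS[op], n) for op, n in read.cigar]
    a.query_sequence = read.query
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(min(q, 93) + 33) for q in read.quals)
    )
    a.set_tag("RG", read.sample_id)
    if read.haplotype is not None:
        a.set_tag("XH", read.haplotype)
    if read.fragment_id is not None:
        a.set_tag("XF", read.fragment_id)
    if read.isoform_id is not None:
        a.set_tag("XI", read.isoform_id)
    return a


def write_sam(reads: list[AlignedRead], locus: LocusModel, path: str,
              sample_ids: list[str]) -> None:
    header = sam_header(locus, sample_ids)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in sorted(reads, key=lambda x: (x.start, x.read_id)):
            out.write(to_segment(r, header))


def read_sam(path: str) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = [(_OPS_REV[op], n) for op, n in a.cigartuples or []]
            reads.append(
                AlignedRead(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    start=a.reference_start + 1,
                    strand="-" if a.is_reverse else "+",
                    sample_id=a.get_tag("RG") if a.has_tag("RG") else "sample",
                    cigar=cigar,
                    query=a.query_sequence or "",
                    quals=list(a.query_qualities or []),
                    is_duplicate=a.is_duplicate,
                    haplotype=a.get_tag("XH") if a.has_tag("XH") else None,
                    fragment_id=a.get_tag("XF") if a.has_tag("XF") else None,
                    isoform_id=a.get_tag("XI") if a.has_tag("XI") else None,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# VCF


def vcf_header(locus: LocusModel, sample_ids: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={locus.contig_name},length={locus.length}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">')
    h.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt allele depths">')
    h.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set (block start)">')
    h.add_line('##FILTER=<ID=low_depth,Description="Depth below threshold in some sample">')
    h.add_line('##FILTER=<ID=phase_inconsistent,Description="Failed phase-consistency filter">')
    for s in sample_ids:
        h.add_sample(s)
    return h


def write_vcf(
    calls: list[VariantCall],
    locus: LocusModel,
    sample_ids: list[str],
    path: str,
    blocks_by_sample: dict[str, list[PhaseBlock]] | None = None,
) -> None:
    """Multi-sample VCF 4.2; when phase blocks are supplied, genotypes of
    phased sites use '|' with PS = block start."""
    header = vcf_header(locus, sample_ids)
    phased: dict[tuple[str, int], tuple[str, int]] = {}
    if blocks_by_sample:
        for sid, blocks in blocks_by_sample.items():
            for b in blocks:
                for pos, gt in b.phased_sites:
                    phased[(sid, pos)] = (gt, b.start)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted(calls, key=lambda x: x.pos):
            rec = out.new_record(
                contig=locus.contig_name,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref_allele),
                alleles=(c.ref_allele, c.alt_allele),
            )
            flags = {f for f in c.qual_flags.values() if f != "pass"}
            if not flags:
                rec.filter.add("PASS")
            else:
                for f in sorted(flags):
                    if f in ("low_depth", "phase_inconsistent"):
                        rec.filter.add(f)
            for s in sample_ids:
                gt = c.genotypes.get(s, "./.")
                key = (s, c.pos)
                if key in phased and gt == "0/1":
                    pgt, ps = phased[key]
                    alleles = tuple(int(x) for x in pgt.split("|"))
                    rec.samples[s]["GT"] = alleles
                    rec.samples[s].phased = True
                    rec.samples[s]["PS"] = ps
                else:
                    if gt == "./.":
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = tuple(int(x) for x in gt.split("/"))
                if s in c.depths:
                    rec.samples[s]["DP"] = c.depths[s]
                if s in c.allele_depths:
                    rec.samples[s]["AD"] = list(c.allele_depths[s])
            out.write(rec)


def read_vcf(path: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            c = VariantCall(
                contig=rec.contig,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0] if rec.alts else ".",
            )
            filters = set(rec.filter.keys())
            for s in rec.samples:
                sm = rec.samples[s]
                gt = sm.get("GT")
                if gt is None or gt[0] is None:
                    c.genotypes[s] = "./."
                else:
                    sep = "|" if sm.phased else "/"
                    c.genotypes[s] = sep.join(str(a) for a in gt)
                if sm.get("DP") is not None:
                    c.depths[s] = sm["DP"]
                ad = sm.get("AD")
                if ad is not None and ad[0] is not None:
                    c.allele_depths[s] = (ad[0], ad[1])
                c.qual_flags[s] = "pass" if not filters or filters == {"PASS"} \
                    else sorted(filters)[0]
            calls.append(c)
    return calls
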