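"""Construction of the synthetic diploid gene locus.

The default locus emulates a ~114 kb minus-strand gene with six exons,
multiple annotated first exons, four annotated 3' UTR lengths (300 bp to
2.6 kb), a (TTG)16 triplet repeat and a polymorphic CT-rich
low-complexity region in the large intron 4, plus novel intron-internal
start and end exons.  Every junction used by any planted isoform gets a
canonical splice motif on the transcribed strand (GT-AG, one GC-AG),
except one deliberately noncanonical decoy junction.

All coordinates below are 1-based inclusive on the synthetic contig.
"""

from __future__ import annotations

import numpy as np

from .models import GeneModel, Interval, LocusModel
from .sequence import random_cds, random_dna, revcomp

DEFAULT_LENGTH = 114_000
CONTIG = "locus"

# canonical exons, ascending genomic order (minus-strand gene: exon 6 first)
EXON6 = Interval(4_000, 6_699)
EXON5 = Interval(30_000, 30_083)
EXON4 = Interval(95_000, 95_119)
EXON3 = Interval(100_000, 100_125)
EXON2 = Interval(104_000, 104_139)
EXON1 = Interval(109_000, 109_599)
CANONICAL_EXONS = [EXON6, EXON5, EXON4, EXON3, EXON2, EXON1]

# alternative annotated first exons (each splices into the exon-2 acceptor)
ALT_FIRST_A = Interval(107_000, 107_399)
ALT_FIRST_B = Interval(105_500, 105_799)

# novel (unannotated) intron-4 exons
NOVEL_START_EXON = Interval(60_000, 60_497)  # novel 5' start, splices to exon 5
NOVEL_END_EXON = Interval(88_000, 88_399)  # novel 3' terminal exon off the exon-4 donor

# decoy first-exon replacement whose downstream junction is noncanonical
DECOY_EXON2B = Interval(103_000, 103_139)

# transcript 3' ends within exon 6 giving UTR lengths 300/1000/1800/2600
CDS_START = 104_089  # first base of ATG, transcript direction (minus strand)
CDS_STOP = 6_696  # first base of the stop codon
UTR3_ENDS = [6_394, 5_694, 4_894, 4_094]

STR_REGION = Interval(50_000, 50_047)  # (TTG)16
STR_UNIT = "TTG"
STR_REF_UNITS = 16
CT_RICH_REGION = Interval(70_000, 70_228)  # 229 bp, matches catalog haplotype 1

PROTEIN_LENGTH = 141


def _complement(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


def _intron(upstream: Interval, downstream: Interval) -> Interval:
    """Intron between two exons given in *transcript* order on the minus
    strand (upstream exon has the higher genomic coordinates)."""
    return Interval(downstream.end + 1, upstream.start - 1)


def planted_introns() -> list[tuple[Interval, str]]:
    """All intron intervals used by planted isoforms with their
    transcribed-strand motifs ('GT-AG', 'GC-AG' or 'AT-AG' for the decoy)."""
    introns = [
        (_intron(EXON1, EXON2), "GT-AG"),
        (_intron(ALT_FIRST_A, EXON2), "GT-AG"),
        (_intron(ALT_FIRST_B, EXON2), "GT-AG"),
        (_intron(EXON2, EXON3), "GC-AG"),  # one GC-AG donor, shared with the skip-3 junction
        (_intron(EXON2, EXON4), "GC-AG"),
        (_intron(EXON3, EXON4), "GT-AG"),
        (_intron(EXON4, EXON5), "GT-AG"),
        (_intron(EXON4, EXON6), "GT-AG"),
        (_intron(EXON5, EXON6), "GT-AG"),
        (_intron(NOVEL_START_EXON, EXON5), "GT-AG"),
        (_intron(EXON4, NOVEL_END_EXON), "GT-AG"),
        (_intron(EXON1, DECOY_EXON2B), "GT-AG"),
        (_intron(DECOY_EXON2B, EXON3), "AT-AG"),  # noncanonical decoy donor
    ]
    return introns


def _ct_catalog(rng: np.random.Generator) -> dict[int, str]:
    """Four CT-rich haplotype sequences with pairwise-distinct lengths so
    size alone separates heterozygous clusters."""
    units = ["CT", "CTT", "CCT", "TC"]
    parts: list[str] = []
    total = 0
    while total < CT_RICH_REGION.length:
        u = units[rng.integers(0, len(units))]
        parts.append(u)
        total += len(u)
    hap1 = "".join(parts)[: CT_RICH_REGION.length]  # 229 bp

    def subs(seq: str, offsets: list[int]) -> str:
        out = list(seq)
        for o in offsets:
            out[o] = "T" if out[o] == "C" else "C"
        return "".join(out)

    # lengths 229/217/241/253: pairwise length gaps of >= 12 so size alone
    # separates heterozygous clusters even under per-read indel noise, and
    # pairwise edit distances >> the 5% similarity cutoff
    hap2 = subs(hap1[:40] + hap1[52:], [10, 60, 110, 160, 190, 205])  # 217 bp
    hap3 = subs(hap1[:100] + "CTTTCTTTCTTT" + hap1[100:], [5, 55, 130, 180, 220, 235])  # 241 bp
    hap4 = subs(
        hap1[:150] + "CTTCTTCCTTCCTTTCCTTCTTTC" + hap1[150:],
        [15, 45, 95, 125, 185, 215, 225, 245],
    )  # 253 bp
    return {1: hap1, 2: hap2, 3: hap3, 4: hap4}


def build_locus(seed: int = 1, length: int = DEFAULT_LENGTH) -> LocusModel:
    """Build the synthetic locus deterministically from ``seed``.

    Raises ``ValueError`` when ``length`` cannot host the planted gene
    architecture.
    """
    if length < 20_000:
        raise ValueError("length too small to host a 6-exon gene plus repeat regions")
    if length < EXON1.end + 2_000:
        raise ValueError(
            f"length {length} too small for the default architecture "
            f"(needs >= {EXON1.end + 2_000})"
        )
    rng = np.random.default_rng(seed)
    seq = list(random_dna(rng, length))

    # 1. plant the coding sequence (codon-aligned exons: exon-local codons,
    #    so exon skipping removes whole codons and never creates new stops)
    cds = "ATG" + random_cds(rng, PROTEIN_LENGTH - 1) + "TAA"
    assert len(cds) == (PROTEIN_LENGTH + 1) * 3
    coding_blocks = [  # (genomic high, genomic low) in transcript order
        (CDS_START, EXON2.start),
        (EXON3.end, EXON3.start),
        (EXON4.end, EXON4.start),
        (EXON5.end, EXON5.start),
        (EXON6.end, CDS_STOP - 2),
    ]
    t = 0
    for hi, lo in coding_blocks:
        for g in range(hi, lo - 1, -1):
            seq[g - 1] = _complement(cds[t])
            t += 1
    assert t == len(cds)

    # 2. splice motifs: transcribed-strand donor XY / acceptor AG map to
    #    genomic revcomp at the intron's high (donor) and low (acceptor) ends
    for intron, motif in planted_introns():
        donor, acceptor = motif.split("-")
        gdonor = revcomp(donor)  # plant at [high-1, high]
        gacceptor = revcomp(acceptor)  # plant at [low, low+1]
        seq[intron.end - 2] = gdonor[0]
        seq[intron.end - 1] = gdonor[1]
        seq[intron.start - 1] = gacceptor[0]
        seq[intron.start] = gacceptor[1]

    # 3. triplet repeat with non-repeat guard flanks
    str_seq = STR_UNIT * STR_REF_UNITS
    seq[STR_REGION.start - 1 : STR_REGION.end] = list(str_seq)
    seq[STR_REGION.start - 3 : STR_REGION.start - 1] = list("CC")
    seq[STR_REGION.end : STR_REGION.end + 2] = list("AA")

    # 4. CT-rich region = catalog haplotype 1
    catalog = _ct_catalog(np.random.default_rng(20190709))  # fixed: the catalog is an annotation
    seq[CT_RICH_REGION.start - 1 : CT_RICH_REGION.end] = list(catalog[1])

    gene = GeneModel(
        exons=list(CANONICAL_EXONS),
        strand="-",
        alt_first_exons=[ALT_FIRST_A, ALT_FIRST_B],
        utr3_end_options=list(UTR3_ENDS),
        cds_start=CDS_START,
        cds_stop=CDS_STOP,
        protein_length_aa=PROTEIN_LENGTH,
    )
    return LocusModel(
        contig_name=CONTIG,
        ref_seq="".join(seq),
        gene=gene,
        strand="-",
        ct_rich_region=CT_RICH_REGION,
        str_region=STR_REGION,
        str_unit=STR_UNIT,
        reference_unit_count=STR_REF_UNITS,
        ct_haplotype_catalog=catalog,
    )


# ---------------------------------------------------------------------------
# planted isoform repertoire


def isoform_chains(gene: GeneModel) -> dict[str, list[Interval]]:
    """Exon chains (ascending genomic order) of the planted repertoire.

    13 structurally valid isoforms (8 AllExons start x UTR combinations,
    one exon-3 skip, two exon-5 skips, one novel intron-internal start,
    one novel 3' end) plus two decoys: one with a noncanonical junction
    and one meant to be planted below the full-length support threshold.
    """

    def all_exons(first: Interval, utr_end: int) -> list[Interval]:
        return [Interval(utr_end, EXON6.end), EXON5, EXON4, EXON3, EXON2, first]

    u300, u1000, u1800, u2600 = UTR3_ENDS
    chains: dict[str, list[Interval]] = {
        "iso_E1_u300": all_exons(EXON1, u300),
        "iso_E1_u1000": all_exons(EXON1, u1000),
        "iso_E1_u1800": all_exons(EXON1, u1800),
        "iso_E1_u2600": all_exons(EXON1, u2600),
        "iso_A1a_u300": all_exons(ALT_FIRST_A, u300),
        "iso_A1a_u2600": all_exons(ALT_FIRST_A, u2600),
        "iso_A1b_u1000": all_exons(ALT_FIRST_B, u1000),
        "iso_A1b_u2600": all_exons(ALT_FIRST_B, u2600),
        "iso_skip3_u300": [Interval(u300, EXON6.end), EXON5, EXON4, EXON2, EXON1],
        "iso_skip5_u300": [Interval(u300, EXON6.end), EXON4, EXON3, EXON2, EXON1],
        "iso_skip5_A1a_u1000": [Interval(u1000, EXON6.end), EXON4, EXON3, EXON2, ALT_FIRST_A],
        "iso_novelstart_u1000": [Interval(u1000, EXON6.end), EXON5, NOVEL_START_EXON],
        "iso_novelend": [NOVEL_END_EXON, EXON4, EXON3, EXON2, EXON1],
        # decoys
        "iso_decoy_noncanonical": [
            Interval(u300, EXON6.end), EXON5, EXON4, EXON3, DECOY_EXON2B, EXON1,
        ],
        "iso_decoy_lowfl": all_exons(ALT_FIRST_B, u1800),
    }
    return chains


VALID_ISOFORMS = [
    "iso_E1_u300", "iso_E1_u1000", "iso_E1_u1800", "iso_E1_u2600",
    "iso_A1a_u300", "iso_A1a_u2600", "iso_A1b_u1000", "iso_A1b_u2600",
    "iso_skip3_u300", "iso_skip5_u300", "iso_skip5_A1a_u1000",
    "iso_novelstart_u1000", "iso_novelend",
]
DECOY_ISOFORMS = ["iso_decoy_noncanonical", "iso_decoy_lowfl"]

TRUE_CLASSES = {
    "iso_E1_u300": "AllExons", "iso_E1_u1000": "AllExons", "iso_E1_u1800": "AllExons",
    "iso_E1_u2600": "AllExons", "iso_A1a_u300": "AllExons", "iso_A1a_u2600": "AllExons",
    "iso_A1b_u1000": "AllExons", "iso_A1b_u2600": "AllExons",
    "iso_skip3_u300": "Skip3", "iso_skip5_u300": "Skip5", "iso_skip5_A1a_u1000": "Skip5",
    "iso_novelstart_u1000": "Alt5", "iso_novelend": "Alt3",
}


# ---------------------------------------------------------------------------
# reference export


def write_fasta(locus: LocusModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{locus.contig_name}\n")
        for i in range(0, locus.length, 70):
            fh.write(locus.ref_seq[i : i + 70] + "\n")


def write_gff3(locus: LocusModel, path: str) -> None:
    """Gene model plus every planted isoform as an mRNA with exon children."""
    g = locus.gene
    lines = ["##gff-version 3"]
    gene_start = min(e.start for e in g.exons)
    gene_end = max(e.end for e in g.exons + g.alt_first_exons)
    lines.append(
        f"{locus.contig_name}\tlocuskit\tgene\t{gene_start}\t{gene_end}\t.\t{g.strand}\t.\t"
        "ID=gene1;Name=synthetic_gene"
    )
    for iso_id, chain in isoform_chains(g).items():
        lo = min(e.start for e in chain)
        hi = max(e.end for e in chain)
        lines.append(
            f"{locus.contig_name}\tlocuskit\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={iso_id};Parent=gene1"
        )
        for k, e in enumerate(chain, 1):
            lines.append(
                f"{locus.contig_name}\tlocuskit\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t"
                f"ID={iso_id}.exon{k};Parent={iso_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
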