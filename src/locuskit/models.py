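"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere in memory and in SAM/VCF
output; BED exports are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Interval:
    """Closed genomic interval, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class GeneModel:
    """Six-exon gene model on one strand of a single contig.

    ``exons`` are the canonical reference exons in ascending genomic
    order.  For a minus-strand gene, transcription order is the reverse:
    exon 1 (the 5' exon) is the last interval in ``exons``.

    ``alt_first_exons`` are alternative annotated first exons (each
    splices into the exon-2 acceptor).  ``utr3_end_options`` are the
    annotated transcript 3' end coordinates; on the minus strand these
    lie below the stop codon within the terminal exon.
    """

    exons: list[Interval]
    strand: str
    alt_first_exons: list[Interval] = field(default_factory=list)
    utr3_end_options: list[int] = field(default_factory=list)
    cds_start: int = 0  # genomic coordinate of the first base of the start codon
    cds_stop: int = 0  # genomic coordinate of the first base of the stop codon
    protein_length_aa: int = 141

    def exon_by_transcript_order(self, n: int) -> Interval:
        """Return exon ``n`` (1-based, transcription order)."""
        if self.strand == "-":
            return self.exons[len(self.exons) - n]
        return self.exons[n - 1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class LocusModel:
    """Reference contig plus planted gene and repeat regions."""

    contig_name: str
    ref_seq: str
    gene: GeneModel
    strand: str
    ct_rich_region: Interval
    str_region: Interval
    str_unit: str = "TTG"
    reference_unit_count: int = 16
    # catalog of known CT-rich haplotype sequences, id -> sequence
    ct_haplotype_catalog: dict[int, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.ref_seq)

    def slice(self, iv: Interval) -> str:
        return self.ref_seq[iv.start - 1 : iv.end]


@dataclass(frozen=True)
class Variant:
    """A planted or called short variant on the reference.

    ``ref`` and ``alt`` are plain allele strings (VCF-style, no anchor
    base convention: a deletion has len(ref) > len(alt) etc.).  For
    region replacements (STR contraction/expansion, CT-rich haplotype
    swap) ``ref`` spans the whole region.
    """

    pos: int
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample (diploid)."""

    sample_id: str
    condition: str  # PD, DLB or N
    haplotypes: tuple[list[Variant], list[Variant]]
    str_unit_counts: tuple[int, int]
    ct_haplotype_ids: tuple[int, int]
    isoform_mix: dict[str, float] = field(default_factory=dict)


@dataclass
class ReadSimConfig:
    """Read simulator knobs; the defaults are the study conditions."""

    seed: int = 1
    gdna_mean_fragment: int = 6000
    gdna_fragment_sd: int = 600
    gdna_mean_coverage: float = 40.0
    duplicate_rate: float = 0.1
    substitution_error_rate: float = 0.006
    indel_error_rate: float = 0.005
    flnc_reads_per_sample: int = 2000
    flnc_end_jitter: int = 15
    # Phred QV ranges: correct calls are high-confidence, errors low
    qv_correct: tuple[int, int] = (30, 93)
    qv_error: tuple[int, int] = (3, 20)
    # intervals with zero capture (probe dropout); fragments overlapping are rejected
    dropout_intervals: list[Interval] = field(default_factory=list)
    # "expected" = deterministic largest-remainder allocation of isoform
    # mixes; "multinomial" = sampled counts
    flnc_allocation: str = "expected"

    def __post_init__(self) -> None:
        for r in (self.duplicate_rate, self.substitution_error_rate, self.indel_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass
class AlignedRead:
    """One long read's alignment to the locus.

    ``query`` and ``quals`` are stored in reference (plus-strand)
    orientation.  ``cigar`` is a list of (op, length) with CIGAR ops in
    {M, I, D, N}; M consumes both, I query only, D/N reference only.
    """

    read_id: str
    contig: str
    start: int  # 1-based leftmost reference position
    strand: str
    sample_id: str
    cigar: list[tuple[str, int]]
    query: str
    quals: list[int]
    is_duplicate: bool = False
    # simulator truth annotations (None when read from plain SAM)
    haplotype: Optional[int] = None
    fragment_id: Optional[str] = None
    isoform_id: Optional[str] = None

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        span = sum(n for op, n in self.cigar if op in "MDN")
        return self.start + span - 1

    @property
    def mean_qv(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0

    def reference_span(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass
class CoverageSummary:
    sample_id: str
    mean_unique_coverage: float
    covered_fraction: float


@dataclass
class VariantCall:
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    # per-sample fields
    genotypes: dict[str, str] = field(default_factory=dict)  # "0/0" "0/1" "1/1" "./."
    depths: dict[str, int] = field(default_factory=dict)
    allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict)
    qual_flags: dict[str, str] = field(default_factory=dict)  # pass/low_depth/low_qual/phase_inconsistent

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class PhaseBlock:
    sample_id: str
    contig: str
    start: int
    end: int
    # ordered (pos, allele_on_hap1) with allele 0 = ref first: "0|1" means
    # ref on haplotype 1, alt on haplotype 2
    phased_sites: list[tuple[int, str]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_sites(self) -> int:
        return len(self.phased_sites)


@dataclass
class PhasingSummary:
    sample_id: str
    total_phased_span: int
    fraction_of_region: float
    longest_block: int


@dataclass
class RegionSubsequence:
    read_id: str
    sample_id: str
    sequence: str


@dataclass
class StrGenotype:
    sample_id: str
    region_name: str
    allele1: Optional[str]  # consensus sequence
    allele2: Optional[str]
    unit_count1: Optional[int] = None
    unit_count2: Optional[int] = None
    label1: Optional[str] = None  # catalog label, if a catalog was supplied
    label2: Optional[str] = None
    support1: int = 0
    support2: int = 0
    flag: str = "ok"  # ok | unresolved | extra_clusters | low_support

    def unit_string(self, unit: str) -> str:
        if self.allele1 is None:
            return "unresolved"
        return f"({unit}){self.unit_count1}/({unit}){self.unit_count2}"


@dataclass
class Isoform:
    isoform_id: str
    contig: str
    strand: str
    exon_chain: list[Interval]
    fl_counts: dict[str, int] = field(default_factory=dict)
    splice_class: Optional[str] = None
    orf_status: Optional[str] = None
    protein_length: Optional[int] = None
    novel_flags: set[str] = field(default_factory=set)
    read_ids: list[str] = field(default_factory=list)

    @property
    def total_fl(self) -> int:
        return sum(self.fl_counts.values())

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron intervals (genomic ascending) as (first, last) intron base."""
        out = []
        for a, b in zip(self.exon_chain, self.exon_chain[1:]):
            out.append((a.end + 1, b.start - 1))
        return out

    @property
    def tx_start(self) -> int:
        """Transcript 5' end in genomic coordinates."""
        return self.exon_chain[-1].end if self.strand == "-" else self.exon_chain[0].start

    @property
    def tx_end(self) -> int:
        """Transcript 3' end in genomic coordinates."""
        return self.exon_chain[0].start if self.strand == "-" else self.exon_chain[-1].end


@dataclass
class SnpCallerParams:
    min_base_qv: int = 13
    min_cov: int = 40
    alpha: float = 0.01
    homopolymer_len: int = 4
    homopolymer_flank: int = 1
    min_gt_reads: int = 5
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CdnaSnp:
    contig: str
    pos: int
    ref_base: str
    alt_base: str
    raw_p: float
    n_tested: int
    significant: bool
    pooled_ref: int
    pooled_alt: int
    sample_genotypes: dict[str, str] = field(default_factory=dict)
    sample_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    covering_isoforms: list[str] = field(default_factory=list)
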