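"""Full-length cDNA isoform collapse, filtering, classification,
abundance, junction validation and ORF prediction.

Collapse groups aligned full-length reads by their ordered splice
junction chain (N operations in the alignment), then clusters transcript
5' ends (tolerance 50 bases) and 3' ends (tolerance 100 bases) within a
chain group; cluster modes become the representative ends.  The
tolerances are far below the smallest planted 3' UTR separation
(~300 bases), so genuinely distinct UTR classes never merge while
alignment jitter is absorbed.

Filtering mirrors targeted long-read practice: every junction must carry
a canonical transcribed-strand motif (GT-AG or GC-AG) and an isoform
must be supported by a minimum total of full-length reads (default 20).
A configurable genomic polyA check flags likely internal-priming
artifacts.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .models import AlignedRead, GeneModel, Interval, Isoform, LocusModel
from .sequence import revcomp

logger = logging.getLogger(__name__)

CANONICAL_MOTIFS = {"GT-AG", "GC-AG"}
SPLICE_CLASSES = ["AllExons", "Skip3", "Skip5", "Alt5", "Alt3"]


# ---------------------------------------------------------------------------
# collapse


def _read_segments(read: AlignedRead) -> list[Interval]:
    """Reference exon segments of a spliced alignment (N ops split)."""
    segs: list[Interval] = []
    r = read.start
    seg_start = read.start
    open_seg = False
    for op, n in read.cigar:
        if op in ("M", "D"):
            if not open_seg:
                seg_start = r
                open_seg = True
            r += n
        elif op == "N":
            if open_seg:
                segs.append(Interval(seg_start, r - 1))
                open_seg = False
            r += n
        # I consumes no reference
    if open_seg:
        segs.append(Interval(seg_start, r - 1))
    return segs


def _mode_clusters(values: list[int], tol: int) -> dict[int, int]:
    """Greedy mode-seeded clustering: repeatedly take the most frequent
    remaining value (smallest on ties) as a cluster mode and assign every
    value within ``tol``.  Returns value -> mode."""
    remaining = Counter(values)
    assignment: dict[int, int] = {}
    while remaining:
        mode = min(remaining, key=lambda v: (-remaining[v], v))
        for v in list(remaining):
            if abs(v - mode) <= tol:
                assignment[v] = mode
                del remaining[v]
    return assignment


def collapse_flnc(
    fl_reads: list[AlignedRead],
    contig: str,
    strand: str,
    tol5: int = 50,
    tol3: int = 100,
) -> list[Isoform]:
    """Collapse aligned full-length reads into isoforms.

    The result is independent of input read order: reads are sorted
    internally and cluster modes break ties deterministically.
    Mono-exon reads are grouped by >= 50% reciprocal overlap.
    """
    reads = sorted(fl_reads, key=lambda r: (r.start, r.read_id))
    spliced: dict[tuple, list[AlignedRead]] = defaultdict(list)
    mono: list[AlignedRead] = []
    segments: dict[str, list[Interval]] = {}
    for read in reads:
        segs = _read_segments(read)
        segments[read.read_id] = segs
        if len(segs) == 1:
            mono.append(read)
        else:
            chain = tuple((a.end + 1, b.start - 1) for a, b in zip(segs, segs[1:]))
            spliced[chain].append(read)
    if not spliced and mono:
        logger.warning("only unspliced reads in input: mono-exon isoforms only")

    isoforms: list[Isoform] = []
    idx = 1
    for chain in sorted(spliced):
        members = spliced[chain]
        if strand == "-":
            ends5 = [segments[r.read_id][-1].end for r in members]
            ends3 = [segments[r.read_id][0].start for r in members]
        else:
            ends5 = [segments[r.read_id][0].start for r in members]
            ends3 = [segments[r.read_id][-1].end for r in members]
        a5 = _mode_clusters(ends5, tol5)
        a3 = _mode_clusters(ends3, tol3)
        groups: dict[tuple[int, int], list[AlignedRead]] = defaultdict(list)
        for read, e5, e3 in zip(members, ends5, ends3):
            groups[(a5[e5], a3[e3])].append(read)
        for (m5, m3) in sorted(groups):
            grp = groups[(m5, m3)]
            lo, hi = (m3, m5) if strand == "-" else (m5, m3)
            exon_bounds: list[tuple[int, int]] = []
            starts = [lo] + [a + 1 for (_, a) in chain]
            ends = [d - 1 for (d, _) in chain] + [hi]
            exon_chain = [Interval(s, e) for s, e in zip(starts, ends)]
            fl: Counter = Counter(r.sample_id for r in grp)
            isoforms.append(
                Isoform(
                    isoform_id=f"iso.{idx}",
                    contig=contig,
                    strand=strand,
                    exon_chain=exon_chain,
                    fl_counts=dict(fl),
                    read_ids=[r.read_id for r in grp],
                )
            )
            idx += 1

    # mono-exon reads: greedy reciprocal-overlap grouping
    mono_groups: list[list[AlignedRead]] = []
    for read in mono:
        seg = segments[read.read_id][0]
        placed = False
        for grp in mono_groups:
            rep = segments[grp[0].read_id][0]
            ov = min(seg.end, rep.end) - max(seg.start, rep.start) + 1
            if ov > 0 and ov >= 0.5 * seg.length and ov >= 0.5 * rep.length:
                grp.append(read)
                placed = True
                break
        if not placed:
            mono_groups.append([read])
    for grp in mono_groups:
        starts = [segments[r.read_id][0].start for r in grp]
        ends = [segments[r.read_id][0].end for r in grp]
        lo = min(Counter(starts).most_common(), key=lambda kv: (-kv[1], kv[0]))[0]
        hi = min(Counter(ends).most_common(), key=lambda kv: (-kv[1], kv[0]))[0]
        isoforms.append(
            Isoform(
                isoform_id=f"iso.{idx}",
                contig=contig,
                strand=strand,
                exon_chain=[Interval(lo, hi)],
                fl_counts=dict(Counter(r.sample_id for r in grp)),
                read_ids=[r.read_id for r in grp],
            )
        )
        idx += 1
    return isoforms


# ---------------------------------------------------------------------------
# filtering


def junction_motif(ref_seq: str, intron: tuple[int, int], strand: str) -> str:
    """Transcribed-strand donor/acceptor dinucleotides of an intron given
    as (first, last) 1-based intron base."""
    lo, hi = intron
    if strand == "+":
        donor = ref_seq[lo - 1 : lo + 1]
        acceptor = ref_seq[hi - 2 : hi]
    else:
        donor = revcomp(ref_seq[hi - 2 : hi])
        acceptor = revcomp(ref_seq[lo - 1 : lo + 1])
    return f"{donor}-{acceptor}"


def genomic_polya_fraction(ref_seq: str, isoform: Isoform, window: int = 20) -> int:
    """Number of genomic adenosines (transcribed strand) in the ``window``
    bases immediately downstream of the isoform 3' end."""
    if isoform.strand == "-":
        g = isoform.tx_end
        seg = ref_seq[max(0, g - 1 - window) : g - 1]
        return seg.count("T")
    g = isoform.tx_end
    seg = ref_seq[g : g + window]
    return seg.count("A")


@dataclass
class DroppedIsoform:
    isoform: Isoform
    reason: str


def filter_isoforms(
    isoforms: list[Isoform],
    model: LocusModel,
    min_fl: int = 20,
    polya_max: int = 12,
    polya_window: int = 20,
) -> tuple[list[Isoform], list[DroppedIsoform]]:
    """Retain isoforms with all-canonical junction motifs, total
    full-length support >= ``min_fl``, and no genomic polyA run directly
    downstream of the 3' end (internal-priming artifact)."""
    retained: list[Isoform] = []
    dropped: list[DroppedIsoform] = []
    for iso in isoforms:
        motifs = [junction_motif(model.ref_seq, j, iso.strand) for j in iso.junctions]
        bad = [m for m in motifs if m not in CANONICAL_MOTIFS]
        if bad:
            dropped.append(DroppedIsoform(iso, f"noncanonical:{bad[0]}"))
            continue
        if iso.total_fl < min_fl:
            dropped.append(DroppedIsoform(iso, f"low_fl:{iso.total_fl}"))
            continue
        if genomic_polya_fraction(model.ref_seq, iso, polya_window) >= polya_max:
            dropped.append(DroppedIsoform(iso, "genomic_polya"))
            continue
        retained.append(iso)
    return retained, dropped


# ---------------------------------------------------------------------------
# classification


def _overlaps_any(chain: list[Interval], target: Interval) -> bool:
    return any(e.overlaps(target) for e in chain)


def classify_splice_pattern(isoform: Isoform, gene: GeneModel) -> str:
    """Assign one of the five splice-pattern groups.

    Skipping requires the transcript span to bridge the annotated exon
    (an exon merely outside the transcript's extent is not "skipped");
    precedence is Skip3 > Skip5 > Alt5 > Alt3 > AllExons.
    """
    if gene.n_exons != 6:
        raise ValueError("classification assumes a 6-exon reference gene")
    chain = isoform.exon_chain
    span = Interval(chain[0].start, chain[-1].end)
    exon3 = gene.exon_by_transcript_order(3)
    exon5 = gene.exon_by_transcript_order(5)
    exon6 = gene.exon_by_transcript_order(6)

    def skipped(exon: Interval) -> bool:
        return span.contains(exon.start) and span.contains(exon.end) \
            and not _overlaps_any(chain, exon)

    if skipped(exon3) and _overlaps_any(chain, exon5):
        return "Skip3"
    if skipped(exon5):
        return "Skip5"
    first_exon = chain[-1] if isoform.strand == "-" else chain[0]
    starts = [gene.exon_by_transcript_order(1)] + list(gene.alt_first_exons)
    if not any(first_exon.overlaps(s) for s in starts):
        return "Alt5"
    if not _overlaps_any(chain, exon6):
        return "Alt3"
    return "AllExons"


def annotated_junctions(gene: GeneModel) -> set[tuple[int, int]]:
    """Intron intervals implied by the annotated gene model: canonical
    adjacencies plus each alternative first exon spliced to exon 2."""
    out: set[tuple[int, int]] = set()
    exons = sorted(gene.exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        out.add((a.end + 1, b.start - 1))
    exon2 = gene.exon_by_transcript_order(2)
    for alt in gene.alt_first_exons:
        if gene.strand == "-":
            out.add((exon2.end + 1, alt.start - 1))
        else:
            out.add((alt.end + 1, exon2.start - 1))
    return out


# ---------------------------------------------------------------------------
# abundance


def abundance(isoforms: list[Isoform], by_class: bool = False) -> pd.DataFrame:
    """Percent of per-sample retained full-length reads, optionally
    aggregated by splice class.  Samples with zero retained reads get NaN
    columns (and a warning)."""
    samples = sorted({s for iso in isoforms for s in iso.fl_counts})
    rows = {}
    for iso in isoforms:
        key = iso.splice_class if by_class else iso.isoform_id
        row = rows.setdefault(key, dict.fromkeys(samples, 0))
        for s, n in iso.fl_counts.items():
            row[s] += n
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0)
    totals = df.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("samples with zero retained FL reads: %s", zero)
    pct = 100.0 * df / totals
    if by_class:
        pct = pct.reindex([c for c in SPLICE_CLASSES if c in pct.index])
    return pct


# ---------------------------------------------------------------------------
# junction validation


def validate_junctions(
    isoforms: list[Isoform],
    gene: GeneModel,
    table: dict[tuple[str, int, int], int] | None,
    min_support: int = 10,
) -> pd.DataFrame:
    """Label each junction supported/unsupported against a short-read
    junction-count table; an isoform is confirmed iff all its *novel*
    junctions are supported.  Without a table every junction is
    ``unknown`` and confirmation is undetermined."""
    known = annotated_junctions(gene)
    records = []
    for iso in isoforms:
        confirmed = True
        for j in iso.junctions:
            novel = j not in known
            if table is None:
                status, count = "unknown", None
            else:
                count = table.get((iso.contig, j[0], j[1]), 0)
                status = "supported" if count >= min_support else "unsupported"
                if novel and status != "supported":
                    confirmed = False
            records.append(
                {
                    "isoform_id": iso.isoform_id, "donor": j[0], "acceptor": j[1],
                    "novel": novel, "short_read_count": count, "status": status,
                    "isoform_confirmed": None if table is None else confirmed,
                }
            )
    df = pd.DataFrame.from_records(records)
    if table is not None and len(df):
        conf = {}
        for iso_id, sub in df.groupby("isoform_id"):
            nov = sub[sub["novel"]]
            conf[iso_id] = bool((nov["status"] == "supported").all())
        df["isoform_confirmed"] = df["isoform_id"].map(conf)
    return df


# ---------------------------------------------------------------------------
# ORF prediction


def transcript_sequence(
    isoform: Isoform, ref_seq: str
) -> tuple[str, list[int]]:
    """Spliced transcript sequence in 5'->3' orientation plus, parallel
    to it, the genomic coordinate of every base."""
    if isoform.strand == "-":
        seq_parts = []
        positions: list[int] = []
        for e in reversed(isoform.exon_chain):
            seq_parts.append(revcomp(ref_seq[e.start - 1 : e.end]))
            positions.extend(range(e.end, e.start - 1, -1))
        return "".join(seq_parts), positions
    seq_parts = []
    positions = []
    for e in isoform.exon_chain:
        seq_parts.append(ref_seq[e.start - 1 : e.end])
        positions.extend(range(e.start, e.end + 1))
    return "".join(seq_parts), positions


_STOPS = {"TAA", "TAG", "TGA"}


def _translate_from(seq: str, start: int) -> tuple[int, int | None]:
    """(protein length in aa incl. Met, transcript index of the stop
    codon) translating from ``start``; stop index is None when
    translation runs off the transcript end (lost stop)."""
    aa = 0
    i = start
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            return aa, i
        aa += 1
        i += 3
    return aa, None


def predict_orf(
    isoform: Isoform,
    gene: GeneModel,
    ref_seq: str,
    min_orf_codons: int = 50,
) -> tuple[str, int | None]:
    """ORF status and predicted protein length.

    Translation starts at the annotated start codon when the transcript
    contains it, otherwise at the start of the longest open reading
    frame.  Status:

    - ``canonical``: protein length equals the annotated protein and the
      stop codon is the annotated one;
    - ``frame_maintained_shorter``: same stop codon, shorter protein
      (whole in-frame exons removed);
    - ``truncated``: premature or lost stop, or the transcript 3' end
      precedes the annotated stop;
    - ``none``: no start codon, or no ORF of >= ``min_orf_codons``.
    """
    seq, positions = transcript_sequence(isoform, ref_seq)
    try:
        start_idx = positions.index(gene.cds_start)
        annotated_start = seq[start_idx : start_idx + 3] == "ATG"
    except ValueError:
        start_idx = -1
        annotated_start = False

    if not annotated_start:
        best: tuple[int, int] | None = None  # (aa, start index)
        i = 0
        while True:
            i = seq.find("ATG", i)
            if i < 0:
                break
            aa, stop = _translate_from(seq, i)
            if stop is not None and (best is None or aa > best[0]):
                best = (aa, i)
            i += 1
        if best is None or best[0] < min_orf_codons:
            return "none", None
        start_idx = best[1]

    n_aa, stop_idx = _translate_from(seq, start_idx)
    if stop_idx is None:
        return "truncated", n_aa  # lost stop: ran off the transcript end
    stop_genomic = positions[stop_idx]
    if stop_genomic == gene.cds_stop:
        if n_aa == gene.protein_length_aa:
            return "canonical", n_aa
        return "frame_maintained_shorter", n_aa
    return "truncated", n_aa
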