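"""Noisy long-read simulation over the diploid locus.

Reads are emitted pre-aligned: the simulator knows the true placement of
every fragment on its haplotype of origin, so it can write the exact
reference CIGAR (haplotype indels and repeat-region replacements become
I/D operations; exonic variants are substitutions inside M).  Sequencing
errors are then layered on: substitutions never move alignment
endpoints, and error indels are only applied strictly inside match
segments, so mapping endpoints and splice junctions are exact — the
property the endpoint-deduplication and isoform-collapse oracles rely
on.

Per-base qualities follow a two-regime model: correct calls draw Phred
QV from ``qv_correct`` (default 30-93) and erroneous calls from
``qv_error`` (default 3-20), so QV-based filters at 13 remove roughly
half of the erroneous bases while keeping essentially all correct ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import locus as loc
from .models import AlignedRead, Interval, LocusModel, ReadSimConfig, SampleTruth, Variant
from .sequence import BASES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# haplotype genome: reference + variant list -> sequence and alignment ops


@dataclass
class HaplotypeGenome:
    hap_seq: str
    # alignment of haplotype to reference: ops in {M, I, D}
    ops: list[tuple[str, int]]
    variants: list[Variant] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.hap_seq)


def build_haplotype(ref_seq: str, variants: list[Variant]) -> HaplotypeGenome:
    """Apply sorted, non-overlapping variants to the reference."""
    parts: list[str] = []
    ops: list[tuple[str, int]] = []
    rpos = 0  # 0-based reference cursor

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for v in sorted(variants, key=lambda x: x.pos):
        vstart = v.pos - 1
        if vstart < rpos:
            raise ValueError(f"overlapping variants at {v.pos}")
        if vstart > rpos:
            emit("M", vstart - rpos)
            parts.append(ref_seq[rpos:vstart])
        if len(v.ref) == len(v.alt):
            emit("M", len(v.ref))
            parts.append(v.alt)
        else:
            p = 0
            while p < min(len(v.ref), len(v.alt)) and v.ref[p] == v.alt[p]:
                p += 1
            if p:
                emit("M", p)
                parts.append(v.alt[:p])
            emit("D", len(v.ref) - p)
            if len(v.alt) > p:
                emit("I", len(v.alt) - p)
                parts.append(v.alt[p:])
        rpos = vstart + len(v.ref)
    if rpos < len(ref_seq):
        emit("M", len(ref_seq) - rpos)
        parts.append(ref_seq[rpos:])
    return HaplotypeGenome(hap_seq="".join(parts), ops=ops, variants=list(variants))


def fragment_alignment(
    hap: HaplotypeGenome, hstart: int, hend: int
) -> tuple[int, list[tuple[str, int]], int]:
    """Map a haplotype interval [hstart, hend) (0-based, half-open) to a
    reference placement.

    Returns (0-based ref start, CIGAR over M/I/D, hskip) where ``hskip``
    is the number of leading haplotype bases dropped because the
    fragment started inside an insertion (alignments must be anchored on
    a match base at both ends); trailing unanchored bases are dropped
    implicitly — the caller takes exactly the cigar-consumed query
    length starting at ``hstart + hskip``.
    """
    cigar: list[tuple[str, int]] = []
    ref_start = -1
    first_q = -1
    r = 0
    h = 0
    for op, n in hap.ops:
        if h >= hend:
            break
        if op == "M":
            lo = max(h, hstart)
            hi = min(h + n, hend)
            if lo < hi:
                if ref_start < 0:
                    ref_start = r + (lo - h)
                    first_q = lo
                cigar.append(("M", hi - lo))
            r += n
            h += n
        elif op == "I":
            lo = max(h, hstart)
            hi = min(h + n, hend)
            if lo < hi and ref_start >= 0:
                cigar.append(("I", hi - lo))
            h += n
        else:  # D
            if ref_start >= 0 and hstart < h < hend:
                cigar.append(("D", n))
            r += n
    if ref_start < 0:
        return -1, [], 0
    while cigar and cigar[-1][0] in "DI":
        cigar.pop()
    merged: list[tuple[str, int]] = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ref_start, merged, first_q - hstart


def _query_len(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MI")


# ---------------------------------------------------------------------------
# sequencing error model


def _edit_cigar(cigar: list[tuple[str, int]], qpos: int, kind: str) -> list[tuple[str, int]] | None:
    """Apply a 1-base error indel at query offset ``qpos``; returns None
    when the position is not strictly interior to an M op (such events
    are skipped so endpoints and junctions stay exact)."""
    out: list[tuple[str, int]] = []
    q = 0
    done = False
    for op, n in cigar:
        if op not in "MI":
            out.append((op, n))
            continue
        if not done and op == "M" and q + 1 <= qpos < q + n - 1:
            off = qpos - q
            if kind == "del":
                out += [("M", off), ("D", 1), ("M", n - off - 1)]
            else:
                out += [("M", off), ("I", 1), ("M", n - off)]
            done = True
        else:
            out.append((op, n))
        q += n
    if not done:
        return None
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def apply_errors(
    rng: np.random.Generator,
    query: str,
    cigar: list[tuple[str, int]],
    cfg: ReadSimConfig,
) -> tuple[str, list[int], list[tuple[str, int]]]:
    """Substitution and 1-bp indel errors plus the two-regime QV model."""
    q = np.frombuffer(query.encode(), dtype=np.uint8).copy()
    n = len(q)
    err = np.zeros(n, dtype=bool)

    nsub = rng.binomial(n, cfg.substitution_error_rate)
    if nsub:
        pos = rng.choice(n, size=nsub, replace=False)
        shift = rng.integers(1, 4, size=nsub)
        lut = {ord(b): i for i, b in enumerate(BASES)}
        for p, s in zip(pos, shift):
            cur = lut.get(int(q[p]), 0)
            q[p] = ord(BASES[(cur + int(s)) % 4])
        err[pos] = True

    nind = rng.binomial(n, cfg.indel_error_rate)
    if nind:
        positions = sorted((int(p) for p in rng.choice(n, size=nind, replace=False)), reverse=True)
        for p in positions:
            if rng.random() < 0.5:  # deletion of query base p
                new = _edit_cigar(cigar, p, "del")
                if new is None:
                    continue
                cigar = new
                q = np.delete(q, p)
                err = np.delete(err, p)
            else:  # insertion of a random base before query offset p
                if p == 0:
                    continue
                new = _edit_cigar(cigar, p, "ins")
                if new is None:
                    continue
                cigar = new
                q = np.insert(q, p, ord(BASES[int(rng.integers(0, 4))]))
                err = np.insert(err, p, True)

    lo_c, hi_c = cfg.qv_correct
    lo_e, hi_e = cfg.qv_error
    quals = rng.integers(lo_c, hi_c + 1, size=len(q))
    n_err = int(err.sum())
    if n_err:
        quals[err] = rng.integers(lo_e, hi_e + 1, size=n_err)
    assert _query_len(cigar) == len(q), "cigar/query length mismatch after errors"
    return q.tobytes().decode(), [int(x) for x in quals], cigar


# ---------------------------------------------------------------------------
# gDNA simulation


def simulate_gdna(
    model: LocusModel,
    truths: list[SampleTruth],
    cfg: ReadSimConfig,
    coverage_by_sample: dict[str, float] | None = None,
) -> tuple[list[AlignedRead], dict]:
    """Simulate captured, sheared gDNA alignments with PCR duplicates.

    Returns (reads, truth) where truth maps read_id -> dict with
    fragment_id, haplotype and is_duplicate.  The duplicate label uses
    the same deterministic representative convention as the dedup module
    (highest mean QV, then lowest read id), making it an exact oracle.
    """
    if not truths:
        raise ValueError("no sample truths supplied")
    rng = np.random.default_rng(cfg.seed)
    reads: list[AlignedRead] = []
    truth: dict[str, dict] = {}
    L = model.length

    for st in truths:
        cov = (coverage_by_sample or {}).get(st.sample_id, cfg.gdna_mean_coverage)
        haps = [build_haplotype(model.ref_seq, hv) for hv in st.haplotypes]
        n_frag = int(round(cov * L / cfg.gdna_mean_fragment))
        if n_frag == 0:
            logger.warning("zero coverage requested for %s: no reads emitted", st.sample_id)
            continue
        seen_endpoints: set[tuple[int, int, str]] = set()
        frag_idx = 0
        attempts = 0
        while frag_idx < n_frag and attempts < n_frag * 50:
            attempts += 1
            hap_i = int(rng.integers(0, 2))
            hap = haps[hap_i]
            flen = int(np.clip(rng.normal(cfg.gdna_mean_fragment, cfg.gdna_fragment_sd),
                               500, 3 * cfg.gdna_mean_fragment))
            if flen >= hap.length:
                flen = hap.length - 1
            hstart = int(rng.integers(0, hap.length - flen))
            ref_start0, cigar, hskip = fragment_alignment(hap, hstart, hstart + flen)
            if ref_start0 < 0 or not cigar:
                continue
            start = ref_start0 + 1
            end = start + sum(n for op, n in cigar if op in "MD") - 1
            strand = "+" if rng.random() < 0.5 else "-"
            if any(Interval(start, end).overlaps(d) for d in cfg.dropout_intervals):
                continue
            key = (start, end, strand)
            if key in seen_endpoints:
                continue  # endpoint collisions would be indistinguishable from PCR duplicates
            seen_endpoints.add(key)
            qstart = hstart + hskip
            qbase = hap.hap_seq[qstart : qstart + _query_len(cigar)]
            frag_id = f"{st.sample_id}_f{frag_idx:05d}"
            n_copies = 1 + (1 if rng.random() < cfg.duplicate_rate else 0)
            members: list[AlignedRead] = []
            for c in range(n_copies):
                query, quals, ecigar = apply_errors(rng, qbase, list(cigar), cfg)
                rid = f"{frag_id}" if c == 0 else f"{frag_id}_dup{c}"
                members.append(
                    AlignedRead(
                        read_id=rid, contig=model.contig_name, start=start, strand=strand,
                        sample_id=st.sample_id, cigar=ecigar, query=query, quals=quals,
                        haplotype=hap_i, fragment_id=frag_id,
                    )
                )
            rep = min(members, key=lambda r: (-r.mean_qv, r.read_id))
            for m in members:
                truth[m.read_id] = {
                    "fragment_id": frag_id,
                    "haplotype": hap_i,
                    "is_duplicate": m.read_id != rep.read_id,
                    "sample_id": st.sample_id,
                }
            reads.extend(members)
            frag_idx += 1
    reads.sort(key=lambda r: (r.start, r.read_id))
    return reads, truth


# ---------------------------------------------------------------------------
# full-length cDNA simulation


def _largest_remainder(mix: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in mix.items()}
    out = {k: int(np.floor(x)) for k, x in raw.items()}
    rem = n - sum(out.values())
    order = sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)
    for k in order[:rem]:
        out[k] += 1
    return out


def simulate_flnc(
    model: LocusModel,
    truths: list[SampleTruth],
    cfg: ReadSimConfig,
    extra_counts: dict[str, dict[str, int]] | None = None,
) -> tuple[list[AlignedRead], dict]:
    """Simulate aligned full-length cDNA reads.

    Each read carries the exact exon chain of its source isoform (splice
    junctions are never moved); 5'/3' ends jitter by up to
    ``flnc_end_jitter`` bases; exonic haplotype SNPs are baked into the
    read so isoform-linked variants are phased in truth.
    """
    rng = np.random.default_rng(cfg.seed + 7)
    chains = loc.isoform_chains(model.gene)
    reads: list[AlignedRead] = []
    truth: dict[str, dict] = {}

    for st in truths:
        for iso in st.isoform_mix:
            if iso not in chains:
                raise ValueError(f"isoform_mix references undefined isoform {iso!r}")
        if cfg.flnc_allocation == "multinomial":
            ids = list(st.isoform_mix)
            probs = np.array([st.isoform_mix[i] for i in ids], dtype=float)
            probs = probs / probs.sum()
            cnt = rng.multinomial(cfg.flnc_reads_per_sample, probs)
            counts = dict(zip(ids, (int(c) for c in cnt)))
        else:
            counts = _largest_remainder(st.isoform_mix, cfg.flnc_reads_per_sample)
        for iso, extra in (extra_counts or {}).items():
            if iso not in chains:
                raise ValueError(f"extra_counts references undefined isoform {iso!r}")
            counts[iso] = counts.get(iso, 0) + extra.get(st.sample_id, 0)

        # exonic substitutions per haplotype (indels never fall in exons)
        hap_subs: list[dict[int, str]] = []
        for hv in st.haplotypes:
            hap_subs.append({v.pos: v.alt for v in hv if v.is_snp})

        r_i = 0
        for iso, n_reads in sorted(counts.items()):
            chain = chains[iso]
            for _ in range(n_reads):
                hap_i = int(rng.integers(0, 2))
                subs = hap_subs[hap_i]
                t_left = int(rng.integers(0, cfg.flnc_end_jitter + 1))
                t_right = int(rng.integers(0, cfg.flnc_end_jitter + 1))
                exons = list(chain)
                exons[0] = Interval(exons[0].start + t_left, exons[0].end)
                exons[-1] = Interval(exons[-1].start, exons[-1].end - t_right)
                parts: list[str] = []
                cigar: list[tuple[str, int]] = []
                prev_end = None
                for e in exons:
                    if prev_end is not None:
                        cigar.append(("N", e.start - prev_end - 1))
                    seg = list(model.ref_seq[e.start - 1 : e.end])
                    for pos, alt in subs.items():
                        if e.start <= pos <= e.end:
                            seg[pos - e.start] = alt
                    parts.append("".join(seg))
                    cigar.append(("M", e.length))
                    prev_end = e.end
                query, quals, ecigar = apply_errors(rng, "".join(parts), cigar, cfg)
                rid = f"{st.sample_id}_c{r_i:06d}"
                r_i += 1
                reads.append(
                    AlignedRead(
                        read_id=rid, contig=model.contig_name, start=exons[0].start,
                        strand=model.strand, sample_id=st.sample_id, cigar=ecigar,
                        query=query, quals=quals, haplotype=hap_i, isoform_id=iso,
                    )
                )
                truth[rid] = {
                    "isoform_id": iso, "haplotype": hap_i, "sample_id": st.sample_id,
                }
    reads.sort(key=lambda r: (r.start, r.read_id))
    return reads, truth
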