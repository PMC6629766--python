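"""Diploid short-variant genotyping from deduplicated pileups, a
phase-consistency filter, read-backed phasing, and phase-block statistics.

The genotyper is a deliberately simple fraction-threshold caller for
high-accuracy long reads: at each site with enough QV-filtered depth,
the alternative-allele fraction f decides the genotype (0/0 below 0.2,
0/1 in [0.2, 0.8], 1/1 above 0.8).  Indels are detected from alignment
gaps and genotyped by the same fractions against spanning depth.
Low-complexity repeat regions (the triplet repeat and the CT-rich
region) are masked here and handled by the dedicated repeat haplotyper.

Phasing builds a graph over heterozygous sites: an edge connects two
sites co-covered by at least one read informative at both; the majority
configuration (cis/trans) orients the edge and |cis - trans| weighs it.
Haplotypes propagate over a maximum spanning tree per connected
component; tied edges are removed first.  Components with two or more
sites become phase blocks.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from .models import AlignedRead, Interval, LocusModel, PhaseBlock, PhasingSummary, VariantCall
from .pileup import base_counts, indel_events, read_site_alleles, span_depth
from .sequence import encode

HET_LOW = 0.2
HET_HIGH = 0.8


def _genotype_from_fraction(f: float) -> str:
    if f < HET_LOW:
        return "0/0"
    if f <= HET_HIGH:
        return "0/1"
    return "1/1"


def default_masks(model: LocusModel, flank: int = 30) -> list[Interval]:
    return [
        Interval(max(1, model.str_region.start - flank), model.str_region.end + flank),
        Interval(max(1, model.ct_rich_region.start - flank), model.ct_rich_region.end + flank),
    ]


def _masked(pos: int, masks: list[Interval]) -> bool:
    return any(m.contains(pos) for m in masks)


def pileup_genotype(
    reads: list[AlignedRead],
    model: LocusModel,
    min_depth: int = 10,
    min_base_qv: int = 13,
    masks: list[Interval] | None = None,
) -> list[VariantCall]:
    """Genotype substitutions and short indels per sample.

    Duplicate-flagged reads are excluded.  Raises ``ValueError`` when a
    read names a contig other than the reference's.
    """
    masks = default_masks(model) if masks is None else masks
    kept = [r for r in reads if not r.is_duplicate]
    for r in kept:
        if r.contig != model.contig_name:
            raise ValueError(f"read {r.read_id} aligned to {r.contig!r}, "
                             f"reference is {model.contig_name!r}")
    samples = sorted({r.sample_id for r in kept})
    by_sample = {s: [r for r in kept if r.sample_id == s] for s in samples}
    L = model.length
    ref_codes = encode(model.ref_seq)

    counts = {s: base_counts(by_sample[s], L, min_base_qv) for s in samples}
    depths = {s: c.sum(axis=1) for s, c in counts.items()}

    # --- substitutions ---------------------------------------------------
    pooled = sum(counts.values())
    pooled_depth = pooled.sum(axis=1)
    alt_pool = pooled.copy()
    idx = np.arange(L)
    valid_ref = ref_codes < 4
    alt_pool[idx[valid_ref], ref_codes[valid_ref]] = 0
    candidate = np.zeros(L, dtype=bool)
    for s in samples:
        c = counts[s]
        d = depths[s]
        a = c.copy()
        a[idx[valid_ref], ref_codes[valid_ref]] = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(d > 0, a.max(axis=1) / np.maximum(d, 1), 0.0)
        candidate |= (d >= min_depth) & (f >= HET_LOW)
    candidate &= valid_ref

    calls: list[VariantCall] = []
    for pos0 in np.flatnonzero(candidate):
        pos = int(pos0) + 1
        if _masked(pos, masks):
            continue
        ref_base = model.ref_seq[pos0]
        alt_code = int(np.argmax(alt_pool[pos0]))
        if alt_pool[pos0, alt_code] == 0:
            continue
        alt_base = "ACGT"[alt_code]
        call = VariantCall(contig=model.contig_name, pos=pos,
                          ref_allele=ref_base, alt_allele=alt_base)
        for s in samples:
            d = int(depths[s][pos0])
            ad_ref = int(counts[s][pos0, ref_codes[pos0]])
            ad_alt = int(counts[s][pos0, alt_code])
            call.depths[s] = d
            call.allele_depths[s] = (ad_ref, ad_alt)
            if d < min_depth:
                call.genotypes[s] = "./."
                call.qual_flags[s] = "low_depth"
            else:
                call.genotypes[s] = _genotype_from_fraction(ad_alt / d)
                call.qual_flags[s] = "pass"
        calls.append(call)

    # --- indels from alignment gaps --------------------------------------
    ev_by_sample = {s: indel_events(by_sample[s]) for s in samples}
    sd_by_sample = {s: span_depth(by_sample[s], L) for s in samples}
    all_keys = sorted({k for ev in ev_by_sample.values() for k in ev})
    for key in all_keys:
        anchor, kind, ilen = key
        pos = anchor  # 1-based anchor base before the gap
        if pos < 1 or pos + ilen > L or _masked(pos, masks):
            continue
        supports = {s: sum(ev_by_sample[s].get(key, {}).values()) for s in samples}
        spans = {s: int(sd_by_sample[s][pos - 1]) for s in samples}
        if not any(spans[s] >= min_depth and supports[s] / max(spans[s], 1) >= HET_LOW
                   for s in samples):
            continue
        if kind == "D":
            ref_allele = model.ref_seq[pos - 1 : pos + ilen]
            alt_allele = model.ref_seq[pos - 1]
        else:
            # consensus inserted sequence pooled across samples
            pool_counter: Counter = Counter()
            for s in samples:
                pool_counter.update(ev_by_sample[s].get(key, {}))
            ins_seq = pool_counter.most_common(1)[0][0]
            ref_allele = model.ref_seq[pos - 1]
            alt_allele = ref_allele + ins_seq
        call = VariantCall(contig=model.contig_name, pos=pos,
                          ref_allele=ref_allele, alt_allele=alt_allele)
        for s in samples:
            d = spans[s]
            call.depths[s] = d
            call.allele_depths[s] = (max(d - supports[s], 0), supports[s])
            if d < min_depth:
                call.genotypes[s] = "./."
                call.qual_flags[s] = "low_depth"
            else:
                call.genotypes[s] = _genotype_from_fraction(supports[s] / d)
                call.qual_flags[s] = "pass"
        calls.append(call)

    calls.sort(key=lambda c: c.pos)
    return calls


# ---------------------------------------------------------------------------
# phase-consistency filter


def _pair_configs(
    reads: list[AlignedRead],
    sites: list[tuple[int, str, str]],
    min_base_qv: int,
) -> dict[tuple[int, int], np.ndarray]:
    """2x2 allele-configuration counts for every site pair co-observed on
    at least one read; keys are (i, j) site indices with i < j."""
    obs = read_site_alleles(reads, sites, min_base_qv)
    pairs: dict[tuple[int, int], np.ndarray] = defaultdict(lambda: np.zeros((2, 2), dtype=int))
    for ob in obs:
        for x in range(len(ob)):
            i, ai = ob[x]
            for y in range(x + 1, len(ob)):
                j, aj = ob[y]
                pairs[(i, j)][ai, aj] += 1
    return dict(pairs)


def phase_consistency_filter(
    calls: list[VariantCall],
    reads: list[AlignedRead],
    sample_id: str,
    min_base_qv: int = 13,
    min_pair_reads: int = 8,
    max_minority: float = 0.2,
) -> list[VariantCall]:
    """Flag het SNPs whose allele co-occurrence with *every* nearby het
    partner is inconsistent with two haplotypes.

    For each co-covered het pair with >= ``min_pair_reads`` informative
    reads, the minority-configuration fraction is 1 - (cis+trans
    majority)/total; a call is flagged ``phase_inconsistent`` only when
    all its tested partners leave more than ``max_minority`` of reads in
    minority configurations.  Isolated het calls are left unflagged.
    """
    sreads = [r for r in reads if r.sample_id == sample_id and not r.is_duplicate]
    het = [c for c in calls if c.genotypes.get(sample_id) == "0/1" and c.is_snp]
    sites = [(c.pos, c.ref_allele, c.alt_allele) for c in het]
    pairs = _pair_configs(sreads, sites, min_base_qv)

    verdict: dict[int, list[bool]] = defaultdict(list)  # site idx -> per-partner ok?
    for (i, j), m in pairs.items():
        n = int(m.sum())
        if n < min_pair_reads:
            continue
        cis = int(m[0, 0] + m[1, 1])
        trans = int(m[0, 1] + m[1, 0])
        minority = min(cis, trans) / n
        ok = minority <= max_minority
        verdict[i].append(ok)
        verdict[j].append(ok)
    for idx, c in enumerate(het):
        tests = verdict.get(idx, [])
        if tests and not any(tests):
            c.qual_flags[sample_id] = "phase_inconsistent"
            c.genotypes[sample_id] = "./."
    return calls


# ---------------------------------------------------------------------------
# read-backed phasing


def read_backed_phase(
    calls: list[VariantCall],
    reads: list[AlignedRead],
    sample_id: str,
    contig: str,
    min_base_qv: int = 13,
) -> list[PhaseBlock]:
    """Phase passing het SNPs of one sample into blocks.

    Edges with cis == trans are removed before components are formed;
    haplotype assignments propagate from the lowest-position site of
    each component over a maximum spanning tree (Kruskal).
    """
    sreads = [r for r in reads if r.sample_id == sample_id and not r.is_duplicate]
    het = [c for c in calls
           if c.genotypes.get(sample_id) == "0/1" and c.is_snp
           and c.qual_flags.get(sample_id) == "pass"]
    het.sort(key=lambda c: c.pos)
    sites = [(c.pos, c.ref_allele, c.alt_allele) for c in het]
    if len(sites) < 2:
        return []
    pairs = _pair_configs(sreads, sites, min_base_qv)

    edges = []  # (weight, i, j, same_phase)
    for (i, j), m in pairs.items():
        cis = int(m[0, 0] + m[1, 1])
        trans = int(m[0, 1] + m[1, 0])
        if cis == trans:
            continue
        edges.append((abs(cis - trans), i, j, cis > trans))
    edges.sort(key=lambda e: -e[0])

    parent = list(range(len(sites)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: dict[int, list[tuple[int, bool]]] = defaultdict(list)
    for w, i, j, same in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        tree[i].append((j, same))
        tree[j].append((i, same))

    phase: dict[int, int] = {}
    blocks: list[PhaseBlock] = []
    visited: set[int] = set()
    for root in range(len(sites)):
        if root in visited or root not in tree:
            continue
        stack = [root]
        phase[root] = 0
        members = []
        visited.add(root)
        while stack:
            u = stack.pop()
            members.append(u)
            for v, same in tree[u]:
                if v in visited:
                    continue
                visited.add(v)
                phase[v] = phase[u] if same else 1 - phase[u]
                stack.append(v)
        if len(members) < 2:
            continue
        members.sort()
        blocks.append(
            PhaseBlock(
                sample_id=sample_id,
                contig=contig,
                start=sites[members[0]][0],
                end=sites[members[-1]][0],
                phased_sites=[
                    (sites[m][0], "1|0" if phase[m] == 0 else "0|1") for m in members
                ],
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


def phasing_summary(
    blocks: list[PhaseBlock], region: Interval, sample_id: str
) -> PhasingSummary:
    """Total phased span, fraction of the region, and longest block."""
    if region.length <= 0:
        raise ValueError("region has zero length")
    mine = [b for b in blocks if b.sample_id == sample_id]
    spans = [b.span for b in mine]
    total = int(sum(spans))
    return PhasingSummary(
        sample_id=sample_id,
        total_phased_span=total,
        fraction_of_region=total / region.length,
        longest_block=max(spans) if spans else 0,
    )
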