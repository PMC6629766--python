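"""Repeat and low-complexity region haplotyping.

Regions that defeat pileup genotyping (a polymorphic triplet repeat, a
CT-rich low-complexity stretch) are resolved read-by-read instead: the
query subsequence spanning the region is extracted from every fully
spanning read, subsequences are clustered first by length and then by
edit-distance similarity, a consensus is built per cluster by star
alignment against a central member, and the one or two surviving
clusters per sample become the diploid genotype.  For unit repeats the
allele is the longest exact run of the unit in the consensus; for
catalogued regions each allele is labelled with the nearest catalogue
entry by edit distance.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import edlib

from .models import AlignedRead, Interval, RegionSubsequence, StrGenotype
from .sequence import longest_unit_run

logger = logging.getLogger(__name__)


def extract_spanning(
    reads: list[AlignedRead], region: Interval, flank: int = 20
) -> list[RegionSubsequence]:
    """Query subsequences between the aligned flank anchors of ``region``.

    Only reads whose alignment fully covers [start - flank, end + flank]
    contribute; the returned sequence is the query between the bases
    aligned to the flank anchors (reference positions start-1 and
    end+1 exclusive), so haplotype indels inside the region are
    preserved verbatim.
    """
    lo = region.start - flank
    hi = region.end + flank
    out: list[RegionSubsequence] = []
    for read in reads:
        if read.is_duplicate or read.start > lo or read.end < hi:
            continue
        # walk the cigar collecting query offsets aligned to region bounds
        q_first = None  # query offset of first base at ref >= region.start
        q_last = None  # query offset of last base at ref <= region.end
        r = read.start
        q = 0
        for op, n in read.cigar:
            if op == "M":
                if r + n > region.start and r <= region.end:
                    seg_lo = max(region.start, r)
                    seg_hi = min(region.end, r + n - 1)
                    if q_first is None:
                        q_first = q + (seg_lo - r)
                    q_last = q + (seg_hi - r)
                r += n
                q += n
            elif op == "I":
                if q_first is not None and r <= region.end + 1:
                    q_last = q + n - 1  # insertions inside the region belong to it
                q += n
            elif op in ("D", "N"):
                r += n
        if q_first is None or q_last is None or q_last < q_first:
            continue
        out.append(
            RegionSubsequence(
                read_id=read.read_id,
                sample_id=read.sample_id,
                sequence=read.query[q_first : q_last + 1],
            )
        )
    if not out:
        logger.warning("no reads span region [%d, %d]", region.start, region.end)
    return out


def cluster_by_size_and_similarity(
    subs: list[RegionSubsequence],
    size_tol: int = 2,
    dist_fraction: float = 0.05,
    min_cluster_support: int = 3,
) -> list[list[RegionSubsequence]]:
    """Two-pass clustering: length bins joined when lengths differ by at
    most ``size_tol``, then single-linkage clustering within a bin on
    pairwise edit distance <= ceil(dist_fraction * mean length).
    Clusters below ``min_cluster_support`` members are discarded."""
    if not subs:
        return []
    ordered = sorted(subs, key=lambda s: (len(s.sequence), s.read_id))
    bins: list[list[RegionSubsequence]] = [[ordered[0]]]
    for s in ordered[1:]:
        if len(s.sequence) - len(bins[-1][-1].sequence) <= size_tol:
            bins[-1].append(s)
        else:
            bins.append([s])

    clusters: list[list[RegionSubsequence]] = []
    for group in bins:
        mean_len = sum(len(s.sequence) for s in group) / len(group)
        cutoff = math.ceil(dist_fraction * mean_len)
        # single linkage via union-find
        parent = list(range(len(group)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                d = edlib.align(group[i].sequence, group[j].sequence, k=cutoff)["editDistance"]
                if d != -1 and d <= cutoff:
                    parent[find(i)] = find(j)
        by_root: dict[int, list[RegionSubsequence]] = {}
        for i, s in enumerate(group):
            by_root.setdefault(find(i), []).append(s)
        clusters.extend(by_root.values())

    kept = [c for c in clusters if len(c) >= min_cluster_support]
    if not kept:
        logger.warning("all clusters below min support %d", min_cluster_support)
    kept.sort(key=lambda c: (-len(c), len(c[0].sequence)))
    return kept


def cluster_consensus(cluster: list[RegionSubsequence]) -> str:
    """Star alignment against the member closest to the median length;
    per-column majority base, ties resolved to the anchor's base.

    Insertions relative to the anchor are included when a majority of
    members carries the same inserted sequence after the same anchor
    column."""
    if not cluster:
        raise ValueError("empty cluster")
    seqs = [s.sequence for s in cluster]
    if len(seqs) == 1:
        return seqs[0]
    by_len = sorted(seqs, key=len)
    median_len = len(by_len[len(by_len) // 2])
    anchor = min(seqs, key=lambda s: (abs(len(s) - median_len), s))
    n_anchor = len(anchor)
    # votes[i][base] for anchor column i; deletion votes as ""
    votes: list[Counter] = [Counter() for _ in range(n_anchor)]
    ins_votes: list[Counter] = [Counter() for _ in range(n_anchor + 1)]
    half = len(seqs) / 2
    for seq in seqs:
        res = edlib.align(seq, anchor, task="path")
        a_i = 0
        nice = edlib.getNiceAlignment(res, seq, anchor)
        q_aln = nice["query_aligned"]
        t_aln = nice["target_aligned"]
        ins_here: list[str] = []
        for qc, tc in zip(q_aln, t_aln):
            if tc == "-":  # insertion relative to anchor
                ins_here.append(qc)
            else:
                ins_votes[a_i][("".join(ins_here))] += 1
                ins_here = []
                votes[a_i][qc if qc != "-" else ""] += 1
                a_i += 1
        ins_votes[n_anchor][("".join(ins_here))] += 1
    out: list[str] = []
    for i in range(n_anchor + 1):
        ins, cnt = ins_votes[i].most_common(1)[0]
        if ins and cnt > half:
            out.append(ins)
        if i < n_anchor:
            top = votes[i].most_common()
            best_count = top[0][1]
            tied = [b for b, c in top if c == best_count]
            base = anchor[i] if anchor[i] in tied else tied[0]
            out.append(base)
    return "".join(out)


def count_repeat_units(seq: str, unit: str) -> int:
    """Longest run of consecutive exact copies of ``unit`` in ``seq``."""
    return longest_unit_run(seq, unit)


def genotype_region(
    clusters: list[list[RegionSubsequence]],
    sample_id: str,
    region_name: str,
    unit: str | None = None,
    catalog: dict[int, str] | None = None,
    min_cluster_support: int = 3,
) -> StrGenotype:
    """Diploid genotype from the surviving clusters of one sample.

    Two clusters give a heterozygous call, one cluster a homozygous
    call; more than two keeps the two best-supported and flags the
    sample; zero clusters reports the genotype unresolved.
    """
    ranked = sorted(clusters, key=lambda c: -len(c))
    flag = "ok"
    if not ranked:
        return StrGenotype(sample_id=sample_id, region_name=region_name,
                           allele1=None, allele2=None, flag="unresolved")
    if len(ranked) > 2:
        ranked = ranked[:2]
        flag = "extra_clusters"
    cons = [cluster_consensus(c) for c in ranked]
    support = [len(c) for c in ranked]
    if len(cons) == 1:
        cons = [cons[0], cons[0]]
        support = [support[0], support[0]]
    if min(support) < min_cluster_support:
        flag = "low_support"

    gt = StrGenotype(
        sample_id=sample_id, region_name=region_name,
        allele1=cons[0], allele2=cons[1],
        support1=support[0], support2=support[1], flag=flag,
    )
    if unit is not None:
        c1 = count_repeat_units(cons[0], unit)
        c2 = count_repeat_units(cons[1], unit)
        if c1 < c2:  # allele1 carries the larger count by convention
            gt.allele1, gt.allele2 = gt.allele2, gt.allele1
            gt.support1, gt.support2 = gt.support2, gt.support1
            c1, c2 = c2, c1
        gt.unit_count1, gt.unit_count2 = c1, c2
    if catalog is not None:
        labels = []
        for seq in (gt.allele1, gt.allele2):
            best = min(
                catalog.items(),
                key=lambda kv: edlib.align(seq, kv[1])["editDistance"],
            )
            labels.append(str(best[0]))
        gt.label1, gt.label2 = labels
    return gt


def genotype_samples(
    reads: list[AlignedRead],
    region: Interval,
    region_name: str,
    unit: str | None = None,
    catalog: dict[int, str] | None = None,
    flank: int = 20,
    size_tol: int = 2,
    dist_fraction: float = 0.05,
    min_cluster_support: int = 3,
) -> dict[str, StrGenotype]:
    """Convenience wrapper: extract, cluster and genotype every sample."""
    subs = extract_spanning(reads, region, flank=flank)
    by_sample: dict[str, list[RegionSubsequence]] = {}
    for s in subs:
        by_sample.setdefault(s.sample_id, []).append(s)
    out: dict[str, StrGenotype] = {}
    for sid in sorted(by_sample):
        clusters = cluster_by_size_and_similarity(
            by_sample[sid], size_tol=size_tol, dist_fraction=dist_fraction,
            min_cluster_support=min_cluster_support,
        )
        out[sid] = genotype_region(
            clusters, sid, region_name, unit=unit, catalog=catalog,
            min_cluster_support=min_cluster_support,
        )
    return out
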