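"""PCR duplicate marking by exact mapping endpoints.

Captured gDNA fragments amplified after capture yield reads with
identical reference endpoints; among each group of reads sharing
(sample, contig, start, end, strand) exactly one representative is left
unflagged — the read with the highest mean base quality, ties broken by
the lexicographically smallest read id, so marking is deterministic and
idempotent.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .models import AlignedRead, CoverageSummary, Interval


def mark_duplicates(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Flag duplicates in place (and return the same list, input order
    preserved).  Reads are grouped by (sample_id, contig, start, end,
    strand); opposite-strand or cross-sample endpoint matches are not
    duplicates."""
    groups: dict[tuple, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.sample_id, r.contig, r.start, r.end, r.strand)].append(r)
    for members in groups.values():
        rep = min(members, key=lambda r: (-r.mean_qv, r.read_id))
        for m in members:
            m.is_duplicate = m is not rep
    return reads


def coverage_summary(
    reads: list[AlignedRead], target: Interval, sample_id: str | None = None
) -> CoverageSummary:
    """Mean unique depth and breadth over ``target`` from alignment spans
    (reference-consuming ops), flagged duplicates excluded."""
    if target.length <= 0:
        raise ValueError("empty target interval")
    kept = [r for r in reads if not r.is_duplicate]
    if sample_id is not None:
        kept = [r for r in kept if r.sample_id == sample_id]
    depth = np.zeros(target.length + 1, dtype=np.int64)
    for r in kept:
        lo = max(r.start, target.start)
        hi = min(r.end, target.end)
        if lo > hi:
            continue
        depth[lo - target.start] += 1
        depth[hi - target.start + 1] -= 1
    depth = np.cumsum(depth)[: target.length]
    label = sample_id if sample_id is not None else "all"
    return CoverageSummary(
        sample_id=label,
        mean_unique_coverage=float(depth.mean()),
        covered_fraction=float((depth > 0).mean()),
    )


def coverage_by_sample(reads: list[AlignedRead], target: Interval) -> list[CoverageSummary]:
    samples = sorted({r.sample_id for r in reads})
    return [coverage_summary(reads, target, s) for s in samples]
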