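"""Isoform-level SNP calling from full-length cDNA pileups.

The caller pools QV-filtered base counts from the full-length reads
assigned to retained isoforms.  Every position with filtered coverage of
at least ``min_cov`` is *tested* (their number is the Bonferroni m): the
most frequent non-reference base is compared against the expected
error-only composition with a one-sided Fisher exact test, and a
substitution is called when the Bonferroni-corrected p-value passes
``alpha`` and the site is not inside or adjacent to a homopolymer run of
four or more identical reference bases.  Per-sample genotypes then
follow the full-length read-support rule: 5+ reads for both alleles is
heterozygous, 5+ for exactly one is homozygous, anything else is
inconclusive.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import fisher_exact

from .models import AlignedRead, CdnaSnp, Isoform, LocusModel, SnpCallerParams
from .pileup import base_counts
from .sequence import encode, homopolymer_mask


def flnc_pileup(
    fl_reads: list[AlignedRead],
    length: int,
    params: SnpCallerParams,
    assigned_read_ids: set[str] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """QV-filtered substitution pileup.

    Returns (pooled (L, 4) counts, per-sample counts).  When
    ``assigned_read_ids`` is given, only those reads (the ones collapsed
    into retained isoforms) contribute.  Insertions and deletions never
    enter the counts.
    """
    if assigned_read_ids is not None:
        fl_reads = [r for r in fl_reads if r.read_id in assigned_read_ids]
    samples = sorted({r.sample_id for r in fl_reads})
    per_sample = {
        s: base_counts([r for r in fl_reads if r.sample_id == s], length, params.min_base_qv)
        for s in samples
    }
    pooled = np.zeros((length, 4), dtype=np.int64)
    for c in per_sample.values():
        pooled += c
    return pooled, per_sample


def fisher_p_enrichment(alt: int, ref: int, error_rate: float) -> float:
    """One-sided Fisher exact p for alt-base enrichment over the expected
    sequencing-error composition at this coverage.

    The expected-error cell rounds half away from zero (0.5 reads -> 1),
    so the comparison row is never all-zero at realistic coverages.
    """
    cov = alt + ref
    exp_err = math.floor(error_rate * cov + 0.5)
    table = [[alt, ref], [exp_err, cov - exp_err]]
    return float(fisher_exact(table, alternative="greater")[1])


def genotype_sample(ref_count: int, alt_count: int, min_gt_reads: int = 5) -> str:
    """The full-length read-support genotype rule (a total function)."""
    ref_ok = ref_count >= min_gt_reads
    alt_ok = alt_count >= min_gt_reads
    if ref_ok and alt_ok:
        return "het"
    if ref_ok and not alt_ok:
        return "homo_ref"
    if alt_ok and not ref_ok:
        return "homo_alt"
    return "inconclusive"


def call_snps(
    pooled: np.ndarray,
    per_sample: dict[str, np.ndarray],
    model: LocusModel,
    params: SnpCallerParams,
) -> tuple[list[CdnaSnp], int]:
    """Call substitution SNPs from the pooled pileup.

    Returns (snps, m) where m is the number of tested positions
    (filtered coverage >= min_cov) used for the Bonferroni correction.
    Positions whose reference base is N are skipped.  Homopolymer
    suppression applies after testing: suppressed positions still count
    toward m but are never called.
    """
    L = pooled.shape[0]
    ref_codes = encode(model.ref_seq)
    depth = pooled.sum(axis=1)
    tested = (depth >= params.min_cov) & (ref_codes < 4)
    m = int(tested.sum())
    if m == 0:
        return [], 0
    hp = homopolymer_mask(model.ref_seq, params.homopolymer_len, params.homopolymer_flank)

    alt_counts = pooled.copy()
    idx = np.flatnonzero(tested)
    alt_counts[idx, ref_codes[idx]] = 0
    snps: list[CdnaSnp] = []
    for pos0 in idx:
        alt_code = int(np.argmax(alt_counts[pos0]))
        alt_n = int(alt_counts[pos0, alt_code])
        if alt_n == 0:
            continue
        ref_n = int(pooled[pos0, ref_codes[pos0]])
        p = fisher_p_enrichment(alt_n, ref_n, params.error_rate)
        significant = p <= params.alpha / m
        if not significant or hp[pos0]:
            continue
        snp = CdnaSnp(
            contig=model.contig_name,
            pos=int(pos0) + 1,
            ref_base=model.ref_seq[pos0],
            alt_base="ACGT"[alt_code],
            raw_p=p,
            n_tested=m,
            significant=True,
            pooled_ref=ref_n,
            pooled_alt=alt_n,
        )
        for s, counts in per_sample.items():
            rc = int(counts[pos0, ref_codes[pos0]])
            ac = int(counts[pos0, alt_code])
            snp.sample_counts[s] = (rc, ac)
            snp.sample_genotypes[s] = genotype_sample(rc, ac, params.min_gt_reads)
        snps.append(snp)
    return snps, m


def link_snps_to_isoforms(snps: list[CdnaSnp], isoforms: list[Isoform]) -> list[CdnaSnp]:
    """An isoform covers a SNP iff the position falls inside one of its
    exons; fills ``covering_isoforms`` in place and returns the list."""
    for snp in snps:
        snp.covering_isoforms = [
            iso.isoform_id
            for iso in isoforms
            if any(e.contains(snp.pos) for e in iso.exon_chain)
        ]
    return snps


def unlinkable_pairs(snps: list[CdnaSnp]) -> list[tuple[int, int]]:
    """Pairs of SNP positions with disjoint covering-isoform sets: no
    single transcript molecule can phase them."""
    out = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if not set(snps[i].covering_isoforms) & set(snps[j].covering_isoforms):
                out.append((snps[i].pos, snps[j].pos))
    return out
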