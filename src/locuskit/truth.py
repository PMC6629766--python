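"""Ground-truth study design for the synthetic 12-sample cohort.

The cohort mirrors the study conditions: 4 PD, 4 DLB and 4 normal
samples; three TTG repeat alleles (9, 12, 15 units against a 16-unit
reference); four catalogued CT-rich haplotypes with haplotype 3
appearing only in disease samples; a shared population pool of intronic
SNPs/indels; and four exonic SNPs whose visibility in cDNA depends on
isoform structure (first-exon choice, novel 3' exon, 3' UTR length).
"""

from __future__ import annotations

import numpy as np

from . import locus as loc
from .models import Interval, LocusModel, SampleTruth, Variant
from .sequence import homopolymer_mask

SAMPLE_IDS = [
    "PD-1", "PD-2", "PD-3", "PD-4",
    "N-1", "N-2", "N-3", "N-4",
    "DLB-1", "DLB-2", "DLB-3", "DLB-4",
]

# (TTG)n genotypes per sample; reference carries 16 units
TTG_GENOTYPES: dict[str, tuple[int, int]] = {
    "PD-1": (15, 15), "PD-2": (12, 12), "PD-3": (12, 12), "PD-4": (15, 12),
    "N-1": (15, 12), "N-2": (12, 12), "N-3": (12, 12), "N-4": (12, 12),
    "DLB-1": (12, 12), "DLB-2": (12, 12), "DLB-3": (15, 9), "DLB-4": (12, 12),
}

# CT-rich catalogue assignments; haplotype 3 only in disease samples
CT_GENOTYPES: dict[str, tuple[int, int]] = {
    "PD-1": (1, 2), "PD-2": (1, 1), "PD-3": (3, 1), "PD-4": (2, 4),
    "N-1": (1, 4), "N-2": (2, 2), "N-3": (1, 2), "N-4": (4, 4),
    "DLB-1": (3, 2), "DLB-2": (3, 4), "DLB-3": (1, 4), "DLB-4": (2, 2),
}

# planted isoform mix (identical across samples and haplotypes); class
# totals: AllExons 0.96, Skip5 0.02, Skip3 0.005, Alt5 0.01, Alt3 0.005
ISOFORM_MIX: dict[str, float] = {
    "iso_E1_u300": 0.30, "iso_E1_u1000": 0.12, "iso_E1_u1800": 0.06,
    "iso_E1_u2600": 0.08, "iso_A1a_u300": 0.20, "iso_A1a_u2600": 0.08,
    "iso_A1b_u1000": 0.07, "iso_A1b_u2600": 0.05,
    "iso_skip3_u300": 0.005, "iso_skip5_u300": 0.012, "iso_skip5_A1a_u1000": 0.008,
    "iso_novelstart_u1000": 0.01, "iso_novelend": 0.005,
}

# decoy full-length counts layered on top of the mix: the noncanonical
# decoy gets ample support (dropped for its motif, not its count); the
# low-support decoy gets 19 FL reads in total, one below the threshold
DECOY_COUNTS: dict[str, dict[str, int]] = {
    "iso_decoy_noncanonical": {s: 8 for s in SAMPLE_IDS},
    "iso_decoy_lowfl": {
        s: n for s, n in zip(SAMPLE_IDS, [2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1])
    },
}

N_POOL_SNPS = 282
N_POOL_INDELS = 35
P_HET = 0.35
P_HOM_ALT = 0.10

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

# per-sample genotype of the four exonic SNPs: 0=hom ref, 1=het, 2=hom alt
EXONIC_SNP_GENOTYPES: dict[str, dict[str, int]] = {
    "snp_exon1": {"PD-3": 2, "DLB-2": 2, "PD-4": 1, "N-1": 1, "N-2": 1, "N-3": 1, "DLB-3": 1},
    "snp_alt1a": {"DLB-4": 2, "PD-1": 1, "N-4": 1, "DLB-3": 1},
    "snp_novelend": {"PD-3": 2, "DLB-1": 2, "N-1": 1, "N-2": 1, "N-3": 1, "DLB-3": 1},
    "snp_utr1k": {"PD-1": 2, "DLB-1": 2, "PD-3": 1, "N-1": 1, "N-2": 1, "N-3": 1,
                  "DLB-2": 1, "DLB-3": 1},
}


def exonic_snp_positions(model: LocusModel) -> dict[str, Variant]:
    """Choose the four exonic SNP sites deterministically: first position
    at/after the anchor that is clear of homopolymer context and exon
    boundaries, so the cDNA caller's homopolymer gate never suppresses a
    planted site."""
    mask = homopolymer_mask(model.ref_seq, 4, 2)
    anchors = {
        "snp_exon1": (loc.EXON1, loc.EXON1.start + 300),
        "snp_alt1a": (loc.ALT_FIRST_A, loc.ALT_FIRST_A.start + 200),
        # 3' UTR site ~950 bases past the stop: covered only by UTR >= 1 kb
        "snp_utr1k": (loc.EXON6, loc.CDS_STOP - 3 - 950),
        "snp_novelend": (loc.NOVEL_END_EXON, loc.NOVEL_END_EXON.start + 200),
    }
    out: dict[str, Variant] = {}
    for name, (exon, anchor) in anchors.items():
        pos = anchor
        while mask[pos - 1] or pos > exon.end - 10:
            pos += 1
            if pos > exon.end - 10:
                raise RuntimeError(f"could not place {name} inside its exon")
        ref = model.ref_seq[pos - 1]
        out[name] = Variant(pos=pos, ref=ref, alt=_TRANSVERSION[ref])
    return out


def _exclusion_zones(model: LocusModel, flank: int = 40) -> list[Interval]:
    zones = []
    for chain in loc.isoform_chains(model.gene).values():
        zones.extend(chain)
    zones += [model.str_region, model.ct_rich_region]
    return [Interval(max(1, z.start - flank), min(model.length, z.end + flank)) for z in zones]


def build_variant_pool(model: LocusModel, seed: int) -> list[Variant]:
    """Population pool of intronic SNPs and 1-3 bp indels with >= 15 bp
    spacing, clear of exons, splice motifs and the repeat regions."""
    rng = np.random.default_rng(seed)
    zones = _exclusion_zones(model)
    taken: list[int] = []
    pool: list[Variant] = []

    def ok(pos: int, span: int) -> bool:
        iv = Interval(pos, pos + span)
        if any(z.overlaps(iv) for z in zones):
            return False
        return all(abs(pos - t) >= 15 for t in taken)

    n_snp = n_indel = 0
    while n_snp < N_POOL_SNPS or n_indel < N_POOL_INDELS:
        pos = int(rng.integers(200, model.length - 200))
        want_indel = n_indel < N_POOL_INDELS and rng.random() < 0.15
        span = 4 if want_indel else 1
        if not ok(pos, span):
            continue
        ref = model.ref_seq[pos - 1]
        if want_indel:
            ilen = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                refal = model.ref_seq[pos - 1 : pos + ilen]
                pool.append(Variant(pos=pos, ref=refal, alt=refal[0]))
            else:  # insertion
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, ilen))
                pool.append(Variant(pos=pos, ref=ref, alt=ref + ins))
            n_indel += 1
        else:
            if n_snp >= N_POOL_SNPS:
                continue
            pool.append(Variant(pos=pos, ref=ref, alt=_TRANSVERSION[ref]))
            n_snp += 1
        taken.append(pos)
    pool.sort(key=lambda v: v.pos)
    return pool


def region_replacement(model: LocusModel, region: Interval, alt_seq: str) -> Variant:
    return Variant(pos=region.start, ref=model.slice(region), alt=alt_seq)


def build_sample_truths(model: LocusModel, seed: int) -> list[SampleTruth]:
    """The default 12-sample cohort with full diploid ground truth."""
    rng = np.random.default_rng(seed + 101)
    pool = build_variant_pool(model, seed)
    exonic = exonic_snp_positions(model)

    truths: list[SampleTruth] = []
    for sid in SAMPLE_IDS:
        haps: tuple[list[Variant], list[Variant]] = ([], [])
        for var in pool:
            u = rng.random()
            if u < P_HOM_ALT:
                haps[0].append(var)
                haps[1].append(var)
            elif u < P_HOM_ALT + P_HET:
                haps[int(rng.integers(0, 2))].append(var)
        for name, var in exonic.items():
            state = EXONIC_SNP_GENOTYPES[name].get(sid, 0)
            if state == 2:
                haps[0].append(var)
                haps[1].append(var)
            elif state == 1:
                haps[int(rng.integers(0, 2))].append(var)
        ttg = TTG_GENOTYPES[sid]
        for h in (0, 1):
            if ttg[h] != model.reference_unit_count:
                haps[h].append(
                    region_replacement(model, model.str_region, model.str_unit * ttg[h])
                )
        ct = CT_GENOTYPES[sid]
        for h in (0, 1):
            if ct[h] != 1:
                haps[h].append(
                    region_replacement(
                        model, model.ct_rich_region, model.ct_haplotype_catalog[ct[h]]
                    )
                )
        haps[0].sort(key=lambda v: v.pos)
        haps[1].sort(key=lambda v: v.pos)
        truths.append(
            SampleTruth(
                sample_id=sid,
                condition=sid.split("-")[0],
                haplotypes=haps,
                str_unit_counts=ttg,
                ct_haplotype_ids=ct,
                isoform_mix=dict(ISOFORM_MIX),
            )
        )
    return truths
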