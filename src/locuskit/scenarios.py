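"""Canned study scenarios: one call builds the locus, the 12-sample
cohort truth and a simulator configuration, so analyses, tests and the
acceptance checks all run the same study design."""

from __future__ import annotations

from .locus import build_locus
from .models import LocusModel, ReadSimConfig, SampleTruth
from .truth import DECOY_COUNTS, build_sample_truths


def default_study(
    seed: int,
    length: int = 114_000,
    gdna_mean_coverage: float = 40.0,
    duplicate_rate: float = 0.1,
    flnc_reads_per_sample: int = 2000,
    n_samples: int = 12,
    **cfg_overrides,
) -> tuple[LocusModel, list[SampleTruth], ReadSimConfig, dict[str, dict[str, int]]]:
    """The default 12-sample cohort over the ~114 kb locus.

    Returns (locus, truths, simulator config, decoy isoform counts).
    ``n_samples`` < 12 keeps a prefix of the cohort for scaled-down runs.
    """
    model = build_locus(seed=seed, length=length)
    truths = build_sample_truths(model, seed=seed)[:n_samples]
    sample_ids = {t.sample_id for t in truths}
    cfg = ReadSimConfig(
        seed=seed,
        gdna_mean_coverage=gdna_mean_coverage,
        duplicate_rate=duplicate_rate,
        flnc_reads_per_sample=flnc_reads_per_sample,
        **cfg_overrides,
    )
    decoys = {
        iso: {s: n for s, n in counts.items() if s in sample_ids}
        for iso, counts in DECOY_COUNTS.items()
    }
    return model, truths, cfg, decoys


def high_het_sample(model: LocusModel, truths: list[SampleTruth]) -> SampleTruth:
    """The cohort sample with the most heterozygous SNPs — the natural
    subject for phasing checks."""
    def n_het(t: SampleTruth) -> int:
        h0 = {(v.pos, v.alt) for v in t.haplotypes[0] if v.is_snp}
        h1 = {(v.pos, v.alt) for v in t.haplotypes[1] if v.is_snp}
        return len(h0 ^ h1)

    return max(truths, key=n_het)
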