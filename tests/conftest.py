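"""Shared fixtures: the default locus and a couple of simulations reused
across test modules (session-scoped — simulation is the expensive part)."""

from __future__ import annotations

import pytest

from locuskit.dedup import mark_duplicates
from locuskit.locus import build_locus
from locuskit.scenarios import default_study
from locuskit.simulate import simulate_flnc, simulate_gdna


@pytest.fixture(scope="session")
def model():
    return build_locus(seed=1)


@pytest.fixture(scope="session")
def gdna_two_samples(model):
    """Two samples at 40x with 10% duplicates (deduplicated)."""
    model_, truths, cfg, _ = default_study(seed=7, gdna_mean_coverage=40,
                                           duplicate_rate=0.1, n_samples=2)
    reads, truth = simulate_gdna(model_, truths, cfg)
    mark_duplicates(reads)
    return model_, truths, reads, truth


@pytest.fixture(scope="session")
def flnc_cohort(model):
    """Full 12-sample cDNA simulation (400 FL reads/sample) with decoys."""
    model_, truths, cfg, decoys = default_study(seed=13, flnc_reads_per_sample=400)
    reads, truth = simulate_flnc(model_, truths, cfg, extra_counts=decoys)
    return model_, truths, reads, truth


def switch_errors(block, sample_truth) -> int:
    """Independent switch-error count: within a block, count adjacent
    phased sites whose relative haplotype assignment disagrees with the
    planted haplotypes (global flips are free)."""
    h0 = {v.pos for v in sample_truth.haplotypes[0] if v.is_snp}
    h1 = {v.pos for v in sample_truth.haplotypes[1] if v.is_snp}
    errors = 0
    prev = None
    for pos, gt in block.phased_sites:
        het0 = pos in h0 and pos not in h1
        het1 = pos in h1 and pos not in h0
        if not (het0 or het1):
            continue  # homozygous or unplanted site: truth undefined
        truth_hap = 0 if het0 else 1
        called_hap = 0 if gt == "1|0" else 1
        rel = truth_hap ^ called_hap
        if prev is not None and rel != prev:
            errors += 1
        prev = rel
    return errors
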