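"""Pipeline orchestration: simulate -> dedup -> variants -> phase ->
str-genotype -> isoforms -> cdna-snps -> report.

Every stage reads and writes plain standard formats (SAM, VCF, GFF3,
TSV, JSON) in the run directory, so stages are independently runnable
and replaceable; a stage whose upstream output is missing raises an
error naming the stage to run first.  All thresholds are echoed into the
run log, and re-running a stage with unchanged inputs and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import locus as loc
from .cdnasnps import call_snps, flnc_pileup, link_snps_to_isoforms
from .dedup import coverage_by_sample, mark_duplicates
from .isoforms import (
    abundance,
    annotated_junctions,
    classify_splice_pattern,
    collapse_flnc,
    filter_isoforms,
    predict_orf,
    transcript_sequence,
    validate_junctions,
)
from .models import Interval, ReadSimConfig, SnpCallerParams
from .samio import read_sam, read_vcf, write_sam, write_vcf
from .sequence import translate
from .simulate import simulate_flnc, simulate_gdna
from .strhap import genotype_samples
from .truth import DECOY_COUNTS, build_sample_truths
from .variants import (
    phase_consistency_filter,
    phasing_summary,
    pileup_genotype,
    read_backed_phase,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "dedup", "variants", "phase", "str-genotype", "isoforms",
          "cdna-snps", "report"]

# upstream file each stage needs -> stage that produces it
_REQUIRES = {
    "dedup": [("gdna.sam", "simulate")],
    "variants": [("gdna.dedup.sam", "dedup")],
    "phase": [("variants.vcf", "variants"), ("gdna.dedup.sam", "dedup")],
    "str-genotype": [("gdna.dedup.sam", "dedup")],
    "isoforms": [("flnc.sam", "simulate")],
    "cdna-snps": [("flnc.sam", "simulate"), ("retained_reads.txt", "isoforms")],
    "report": [("phasing_summary.tsv", "phase"), ("str_genotypes.tsv", "str-genotype"),
               ("abundance_by_class.tsv", "isoforms"), ("cdna_snps.tsv", "cdna-snps")],
}


@dataclass
class RunConfig:
    """Run parameters; unknown keys in a config file are rejected."""

    seed: int = 1
    out_dir: str = "locuskit_run"
    locus_length: int = 114_000
    n_samples: int = 12
    include_decoys: bool = True
    sim: ReadSimConfig = field(default_factory=ReadSimConfig)
    min_depth: int = 10
    min_base_qv: int = 13
    phase_min_pair_reads: int = 8
    phase_max_minority: float = 0.2
    str_flank: int = 20
    str_size_tol: int = 2
    str_dist_fraction: float = 0.05
    str_min_cluster_support: int = 3
    iso_min_fl: int = 20
    iso_tol5: int = 50
    iso_tol3: int = 100
    snp: SnpCallerParams = field(default_factory=SnpCallerParams)
    junction_table: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for sub_name, sub_cls in (("sim", ReadSimConfig), ("snp", SnpCallerParams)):
            if sub_name in d:
                sub = d.pop(sub_name)
                known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(sub) - known
                if bad:
                    raise ValueError(f"unknown {sub_name} config keys: {sorted(bad)}")
                kwargs[sub_name] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**{**d, **kwargs})

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["sim"]["dropout_intervals"] = [
            [iv.start, iv.end] for iv in self.sim.dropout_intervals
        ]
        return out


def _path(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.out_dir, name)


def _require(cfg: RunConfig, stage: str) -> None:
    for fname, producer in _REQUIRES.get(stage, []):
        if not os.path.exists(_path(cfg, fname)):
            raise FileNotFoundError(
                f"stage {stage!r} needs {fname}; run stage {producer!r} first"
            )


def _model(cfg: RunConfig):
    return loc.build_locus(seed=cfg.seed, length=cfg.locus_length)


def _sample_ids(cfg: RunConfig) -> list[str]:
    from .truth import SAMPLE_IDS

    return SAMPLE_IDS[: cfg.n_samples]


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns the run
    report (also written to report.json after the report stage)."""
    stages = STAGES if stages is None or stages == ["all"] else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"config": cfg.echo(), "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        _require(cfg, stage)
        logger.info("stage %s: params=%s", stage, json.dumps(cfg.echo(), sort_keys=True))
        result = _RUNNERS[stage](cfg)
        report["stages"][stage] = result
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig) -> dict:
    model = _model(cfg)
    truths = build_sample_truths(model, seed=cfg.seed)[: cfg.n_samples]
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    gdna, gtruth = simulate_gdna(model, truths, sim_cfg)
    decoys = None
    if cfg.include_decoys:
        ids = {t.sample_id for t in truths}
        decoys = {iso: {s: n for s, n in c.items() if s in ids}
                  for iso, c in DECOY_COUNTS.items()}
    flnc, ftruth = simulate_flnc(model, truths, sim_cfg, extra_counts=decoys)
    samples = _sample_ids(cfg)
    loc.write_fasta(model, _path(cfg, "reference.fasta"))
    loc.write_gff3(model, _path(cfg, "annotation.gff3"))
    write_sam(gdna, model, _path(cfg, "gdna.sam"), samples)
    write_sam(flnc, model, _path(cfg, "flnc.sam"), samples)
    pd.DataFrame(
        [
            {"read_id": rid, **info}
            for rid, info in sorted(gtruth.items())
        ]
    ).to_csv(_path(cfg, "truth_gdna.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"read_id": rid, **info} for rid, info in sorted(ftruth.items())]
    ).to_csv(_path(cfg, "truth_flnc.tsv"), sep="\t", index=False)
    rows = []
    for t in truths:
        for h in (0, 1):
            for v in t.haplotypes[h]:
                rows.append({"sample_id": t.sample_id, "haplotype": h,
                             "pos": v.pos, "ref": v.ref, "alt": v.alt})
    pd.DataFrame(rows).to_csv(_path(cfg, "truth_variants.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": t.sample_id, "condition": t.condition,
             "ttg_1": t.str_unit_counts[0], "ttg_2": t.str_unit_counts[1],
             "ct_1": t.ct_haplotype_ids[0], "ct_2": t.ct_haplotype_ids[1]}
            for t in truths
        ]
    ).to_csv(_path(cfg, "truth_str.tsv"), sep="\t", index=False)
    return {"gdna_reads": len(gdna), "flnc_reads": len(flnc), "samples": len(truths)}


def _stage_dedup(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "gdna.sam"))
    mark_duplicates(reads)
    write_sam(reads, model, _path(cfg, "gdna.dedup.sam"), _sample_ids(cfg))
    target = Interval(1, model.length)
    summaries = coverage_by_sample(reads, target)
    pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries]
    ).to_csv(_path(cfg, "coverage.tsv"), sep="\t", index=False)
    n_dup = sum(r.is_duplicate for r in reads)
    return {"reads": len(reads), "duplicates_flagged": n_dup}


def _stage_variants(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "gdna.dedup.sam"))
    calls = pileup_genotype(reads, model, min_depth=cfg.min_depth,
                            min_base_qv=cfg.min_base_qv)
    write_vcf(calls, model, _sample_ids(cfg), _path(cfg, "variants.vcf"))
    n_snp = sum(c.is_snp for c in calls)
    return {"variants": len(calls), "snps": n_snp, "indels": len(calls) - n_snp}


def _stage_phase(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "gdna.dedup.sam"))
    calls = read_vcf(_path(cfg, "variants.vcf"))
    samples = _sample_ids(cfg)
    blocks_by_sample = {}
    summaries = []
    region = Interval(1, model.length)
    for s in samples:
        phase_consistency_filter(
            calls, reads, s, min_base_qv=cfg.min_base_qv,
            min_pair_reads=cfg.phase_min_pair_reads,
            max_minority=cfg.phase_max_minority,
        )
        blocks = read_backed_phase(calls, reads, s, model.contig_name,
                                   min_base_qv=cfg.min_base_qv)
        blocks_by_sample[s] = blocks
        summaries.append(phasing_summary(blocks, region, s))
    write_vcf(calls, model, samples, _path(cfg, "phased.vcf"), blocks_by_sample)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        _path(cfg, "phasing_summary.tsv"), sep="\t", index=False
    )
    return {
        "samples": len(samples),
        "blocks": sum(len(b) for b in blocks_by_sample.values()),
        "max_fraction_phased": max((s.fraction_of_region for s in summaries), default=0.0),
    }


def _stage_str(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "gdna.dedup.sam"))
    rows = []
    for region, name, unit, catalog in (
        (model.str_region, "ttg_repeat", model.str_unit, None),
        (model.ct_rich_region, "ct_rich", None, model.ct_haplotype_catalog),
    ):
        genos = genotype_samples(
            reads, region, name, unit=unit, catalog=catalog,
            flank=cfg.str_flank, size_tol=cfg.str_size_tol,
            dist_fraction=cfg.str_dist_fraction,
            min_cluster_support=cfg.str_min_cluster_support,
        )
        for sid, g in genos.items():
            rows.append(
                {
                    "sample_id": sid, "region": name,
                    "genotype": g.unit_string(unit) if unit else f"{g.label1}/{g.label2}",
                    "allele1_support": g.support1, "allele2_support": g.support2,
                    "flag": g.flag,
                }
            )
    pd.DataFrame(rows).to_csv(_path(cfg, "str_genotypes.tsv"), sep="\t", index=False)
    return {"regions": 2, "genotypes": len(rows)}


def _read_junction_table(path: str) -> dict[tuple[str, int, int], int]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.contig, int(r.donor), int(r.acceptor)): int(r.count)
        for r in df.itertuples()
    }


def _stage_isoforms(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "flnc.sam"))
    isoforms = collapse_flnc(reads, model.contig_name, model.strand,
                             tol5=cfg.iso_tol5, tol3=cfg.iso_tol3)
    retained, dropped = filter_isoforms(isoforms, model, min_fl=cfg.iso_min_fl)
    known = annotated_junctions(model.gene)
    for iso in retained:
        iso.splice_class = classify_splice_pattern(iso, model.gene)
        iso.orf_status, iso.protein_length = predict_orf(iso, model.gene, model.ref_seq)
        for j in iso.junctions:
            if j not in known:
                iso.novel_flags.add("novel_junction")

    # GFF3 of retained isoforms
    lines = ["##gff-version 3"]
    for iso in retained:
        lo = min(e.start for e in iso.exon_chain)
        hi = max(e.end for e in iso.exon_chain)
        attrs = (f"ID={iso.isoform_id};splice_class={iso.splice_class};"
                 f"orf_status={iso.orf_status};total_fl={iso.total_fl}")
        lines.append(f"{iso.contig}\tlocuskit\tmRNA\t{lo}\t{hi}\t.\t{iso.strand}\t.\t{attrs}")
        for k, e in enumerate(iso.exon_chain, 1):
            lines.append(
                f"{iso.contig}\tlocuskit\texon\t{e.start}\t{e.end}\t.\t{iso.strand}\t.\t"
                f"ID={iso.isoform_id}.exon{k};Parent={iso.isoform_id}"
            )
    with open(_path(cfg, "isoforms.gff3"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    abundance(retained, by_class=False).to_csv(_path(cfg, "abundance.tsv"), sep="\t")
    abundance(retained, by_class=True).to_csv(_path(cfg, "abundance_by_class.tsv"), sep="\t")
    table = _read_junction_table(cfg.junction_table) if cfg.junction_table else None
    validate_junctions(retained, model.gene, table).to_csv(
        _path(cfg, "junction_report.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [{"isoform_id": d.isoform.isoform_id, "total_fl": d.isoform.total_fl,
          "reason": d.reason} for d in dropped]
    ).to_csv(_path(cfg, "dropped_isoforms.tsv"), sep="\t", index=False)
    with open(_path(cfg, "proteins.fasta"), "w") as fh:
        for iso in retained:
            seq, _ = transcript_sequence(iso, model.ref_seq)
            fh.write(f">{iso.isoform_id} orf_status={iso.orf_status}\n")
            fh.write((translate(seq) or "-") + "\n")
    with open(_path(cfg, "retained_reads.txt"), "w") as fh:
        for iso in retained:
            for rid in sorted(iso.read_ids):
                fh.write(f"{rid}\t{iso.isoform_id}\n")
    return {"collapsed": len(isoforms), "retained": len(retained), "dropped": len(dropped)}


def _stage_cdna_snps(cfg: RunConfig) -> dict:
    model = _model(cfg)
    reads = read_sam(_path(cfg, "flnc.sam"))
    assigned = set()
    with open(_path(cfg, "retained_reads.txt")) as fh:
        for line in fh:
            assigned.add(line.split("\t")[0].strip())
    pooled, per_sample = flnc_pileup(reads, model.length, cfg.snp, assigned)
    snps, m = call_snps(pooled, per_sample, model, cfg.snp)
    # link against retained isoforms re-read from the GFF
    import re

    isoforms = []
    from .models import Isoform

    with open(_path(cfg, "isoforms.gff3")) as fh:
        current = None
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] == "mRNA":
                iso_id = re.search(r"ID=([^;]+)", f[8]).group(1)
                current = Isoform(isoform_id=iso_id, contig=f[0], strand=f[6],
                                  exon_chain=[])
                isoforms.append(current)
            elif f[2] == "exon" and current is not None:
                current.exon_chain.append(Interval(int(f[3]), int(f[4])))
    link_snps_to_isoforms(snps, isoforms)
    rows = []
    for i, snp in enumerate(snps, 1):
        by_gt: dict[str, list[str]] = {"homo_ref": [], "homo_alt": [], "het": [],
                                       "inconclusive": []}
        for s, g in snp.sample_genotypes.items():
            by_gt[g].append(s)
        rows.append(
            {
                "#": i, "coord": snp.pos, "ref": snp.ref_base, "alt": snp.alt_base,
                "raw_p": snp.raw_p, "n_tested": m,
                "homo_ref": ",".join(sorted(by_gt["homo_ref"])),
                "homo_alt": ",".join(sorted(by_gt["homo_alt"])),
                "het": ",".join(sorted(by_gt["het"])),
                "inconclusive": ",".join(sorted(by_gt["inconclusive"])),
                "covering_isoforms": ",".join(snp.covering_isoforms),
            }
        )
    pd.DataFrame(rows).to_csv(_path(cfg, "cdna_snps.tsv"), sep="\t", index=False)
    return {"tested_positions": m, "snps_called": len(snps)}


def _stage_report(cfg: RunConfig) -> dict:
    tables = {
        "phasing_summary": "phasing_summary.tsv",
        "str_genotypes": "str_genotypes.tsv",
        "abundance_by_class": "abundance_by_class.tsv",
        "cdna_snps": "cdna_snps.tsv",
        "coverage": "coverage.tsv",
    }
    out = {"parameters": cfg.echo(), "tables": {}}
    for key, fname in tables.items():
        df = pd.read_csv(_path(cfg, fname), sep="\t")
        out["tables"][key] = df.to_dict(orient="records")
    with open(_path(cfg, "report.json"), "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return {"tables": sorted(tables)}


_RUNNERS = {
    "simulate": _stage_simulate,
    "dedup": _stage_dedup,
    "variants": _stage_variants,
    "phase": _stage_phase,
    "str-genotype": _stage_str,
    "isoforms": _stage_isoforms,
    "cdna-snps": _stage_cdna_snps,
    "report": _stage_report,
}
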