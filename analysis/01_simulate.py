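"""Simulate the 12-sample targeted study: a ~114 kb minus-strand 6-exon
gene with planted SNPs/indels, a (TTG)16 triplet repeat, a 4-haplotype
CT-rich region, 15 planted isoforms (2 decoys), sheared ~6 kb gDNA
fragments with PCR duplicates, and full-length cDNA reads with QVs."""

from common import run_config
from locuskit.pipeline import run_pipeline

cfg = run_config()
report = run_pipeline(cfg, stages=["simulate"])["stages"]["simulate"]
print(f"simulated {report['samples']} samples into {cfg.out_dir}")
print(f"  gDNA alignments : {report['gdna_reads']}")
print(f"  FL cDNA reads   : {report['flnc_reads']}")
print("wrote reference.fasta, annotation.gff3, gdna.sam, flnc.sam and truth tables")
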