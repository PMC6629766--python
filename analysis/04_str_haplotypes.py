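"""Resolve the (TTG)n triplet repeat and the CT-rich low-complexity
region by spanning-read clustering and per-cluster consensus."""

import pandas as pd

from common import OUT, run_config
from locuskit.pipeline import run_pipeline

cfg = run_config()
run_pipeline(cfg, stages=["str-genotype"])
df = pd.read_csv(f"{OUT}/str_genotypes.tsv", sep="\t")
print("repeat-region genotypes (allele1/allele2 with read support):")
print(df.to_string(index=False))
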