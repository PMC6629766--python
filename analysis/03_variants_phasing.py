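"""Genotype short variants from deduplicated pileups, filter het calls
for phase consistency, phase them into blocks, and report the phased
fraction of the locus per sample."""

import pandas as pd

from common import OUT, run_config
from locuskit.pipeline import run_pipeline

cfg = run_config()
rep = run_pipeline(cfg, stages=["variants", "phase"])["stages"]
print(f"called {rep['variants']['snps']} SNPs and {rep['variants']['indels']} indels"
      " (repeat regions masked; handled separately)")
summ = pd.read_csv(f"{OUT}/phasing_summary.tsv", sep="\t")
summ["fraction_of_region"] = (100 * summ["fraction_of_region"]).round(1)
print("phasing summary (fraction in % of the 114 kb region):")
print(summ.to_string(index=False))
best = summ.loc[summ["fraction_of_region"].idxmax()]
print(f"best sample: {best.sample_id} with {best.fraction_of_region}% phased, "
      f"longest block {best.longest_block/1000:.1f} kb")
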