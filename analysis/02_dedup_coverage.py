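"""Mark PCR duplicates by exact mapping endpoints and summarise unique
coverage per sample over the whole locus."""

import pandas as pd

from common import OUT, run_config
from locuskit.pipeline import run_pipeline

cfg = run_config()
report = run_pipeline(cfg, stages=["dedup"])["stages"]["dedup"]
cov = pd.read_csv(f"{OUT}/coverage.tsv", sep="\t")
print(f"flagged {report['duplicates_flagged']} of {report['reads']} reads as duplicates")
print("unique coverage per sample:")
print(cov.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
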