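"""Shared run configuration for the numbered analysis scripts.

Everything is written under results/run with one fixed seed; each script
runs one pipeline stage and narrates what it produced.  Coverage and
read depth are set to desk scale (25-fold gDNA, 600 FL reads/sample) —
enough for every downstream stage to resolve the planted truth.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from locuskit.models import ReadSimConfig  # noqa: E402
from locuskit.pipeline import RunConfig  # noqa: E402

SEED = 20190709 % 100_000
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "run")


def run_config() -> RunConfig:
    return RunConfig(
        seed=SEED,
        out_dir=OUT,
        n_samples=12,
        sim=ReadSimConfig(
            gdna_mean_coverage=25,
            duplicate_rate=0.1,
            flnc_reads_per_sample=600,
        ),
    )
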