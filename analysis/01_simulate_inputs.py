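"""Generate the paired synthetic studies and every downstream input.

Two two-condition negative-binomial single-cell datasets (arms A and B) with
planted shared / contrasting / arm-specific effects, a signed regulatory
network with a known top regulator, and post-mortem / GWAS / gene-set
reference lists with planted overlap are written under the output directory.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("simulate", __doc__)
A = pipe.artifacts["studies"]["A"]
truth = pipe.artifacts["truth"]
counts = truth.categories["category"].value_counts().to_dict()
print(f"study A: {A.n_obs} cells x {A.n_vars} genes; planted categories: {counts}")
print(f"inputs written under {pipe.outdir}")
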