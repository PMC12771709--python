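"""Filter cells by detected genes and mitochondrial fraction, then normalize.

Cells are kept when they detect 200-8,000 genes and carry < 5% mitochondrial
counts; survivors are total-count scaled and log1p transformed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("qc", __doc__)
for arm, data in pipe.artifacts["qc"].items():
    before = pipe.artifacts["studies"][arm].n_obs
    print(f"study {arm}: kept {data.n_obs}/{before} cells")
print(f"QC summary under {pipe.outdir}")
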