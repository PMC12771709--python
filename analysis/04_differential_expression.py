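"""Poisson likelihood-ratio differential expression, disease vs control,
separately per study and per annotated cell type, Bonferroni-adjusted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("de", __doc__)
for (arm, ct), tab in pipe.artifacts["de"].items():
    print(f"study {arm} / {ct}: {int(tab.significant.sum())} significant "
          f"of {len(tab)} tested genes")
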