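"""Coverage, directional concordance, and one-sided Fisher overlap of the
organoid DEGs against the post-mortem reference table and the GWAS gene list.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through
from crossorg import round_half_up

pipe = pipeline_through("overlap", __doc__)
for name, rep in pipe.artifacts["overlap"].items():
    print(f"{name}: coverage {round_half_up(rep.coverage_pct, 1)}% "
          f"({rep.n_intersect}/{rep.n_query}), fisher p={rep.fisher_p:.3g}, "
          f"{len(rep.concordant)} concordant / {len(rep.discordant)} discordant")
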