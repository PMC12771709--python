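"""Intersect top-ligand targets with significant ligand-receptor pair genes,
enrich the intersection per study, and extract the top shared pathways.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("ccc", __doc__)
shared = pipe.artifacts["ccc"]
print(f"{len(shared)} shared significant pathway(s):")
for name, row in shared.iterrows():
    print(f"  {name}: p_adj A={row.p_adj_A:.2e}, B={row.p_adj_B:.2e}")
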