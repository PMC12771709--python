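"""Hypergeometric over-representation of shared+contrasting DEGs against the
gene-set collection (min 3 mapped genes, BH adjustment, top-100 extraction).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("enrich", __doc__)
for ct, tab in pipe.artifacts["enrichment"].items():
    top = tab.iloc[0]
    print(f"{ct}: top set {tab.index[0]} (p_adj={top.p_adj:.2e}, "
          f"{top.overlap} mapped genes)")
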