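"""Cluster each study (PCA + k-means scan, silhouette-selected k), annotate
clusters with marker programs, and test condition-by-type composition.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("cluster", __doc__)
for arm, res in pipe.artifacts["cluster"].items():
    sil = ", ".join(f"k={k}: {s:.3f}" for k, s in res.silhouette_by_k.items())
    comp = pipe.artifacts["composition"][arm]
    print(f"study {arm}: chosen k={res.chosen_k} ({sil}); "
          f"composition chi2={comp.chi2:.2f} df={comp.df} p={comp.p:.3g}")
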