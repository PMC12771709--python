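"""Rank signed-network regulators by how many observed DEG signs their
modulation reverts, and flag hub / central / attractor roles.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("network", __doc__)
_, ranking, roles, truth = pipe.artifacts["network"]
for r in ranking[:3]:
    print(f"{r.node}: direction {r.direction}, reverts {r.score} genes")
print(f"planted regulator: {truth.perturbagens[0]['node']} "
      f"(score {truth.perturbagens[0]['score']})")
print(f"attractors: {roles.index[roles.attractor].tolist()}")
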