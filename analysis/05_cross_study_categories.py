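"""Categorize genes as shared / contrasting / study-specific across the two
studies and flag developmental genes with an asterisk.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import pipeline_through

pipe = pipeline_through("compare", __doc__)
for ct, counts in pipe.report["category_counts"].items():
    print(f"{ct}: {counts}")
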