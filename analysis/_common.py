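"""Shared driver plumbing: run the pipeline through a given stage and return it."""

import argparse

from crossorg.pipeline import STAGES, Pipeline


def pipeline_through(stage: str, description: str) -> Pipeline:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/analysis")
    args = ap.parse_args()
    pipe = Pipeline({"seed": args.seed}, outdir=args.outdir)
    for s in STAGES[: STAGES.index(stage) + 1]:
        getattr(pipe, f"stage_{s}")()
    return pipe
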