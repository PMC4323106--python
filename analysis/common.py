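"""Shared argument handling for the numbered analysis drivers.

Each driver is a thin wrapper over :mod:`nemasrna.pipeline`: it parses
the run parameters, executes one pipeline stage (the simulation is
re-derived deterministically from the seed, so stages can run in any
order), and prints the stage's verdict lines.
"""

import argparse
import json
from pathlib import Path

from nemasrna import pipeline


def run_stage(stage: str, description: str) -> dict:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/run"))
    parser.add_argument("--preset", default="clade_v",
                        choices=sorted(pipeline.PRESETS))
    parser.add_argument("--n-reads", type=int, default=100_000)
    args = parser.parse_args()
    config = pipeline.RunConfig(
        out_dir=args.out_dir, seed=args.seed, preset=args.preset,
        n_reads=args.n_reads, stages=(stage,),
    )
    summary = pipeline.run_pipeline(config)
    print(json.dumps(summary, indent=2, sort_keys=True))
    return summary
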