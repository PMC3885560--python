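"""Shared argument handling for the numbered analysis drivers."""

import argparse


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", default="results/cohort",
                        help="artifact directory shared by all steps")
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()
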