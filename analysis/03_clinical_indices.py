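"""Compute insulin-sensitivity indices per subject and summarize by phase.

Matsuda index, QUICKI and HOMA-IR from each subject's OGTT glucose and
insulin series, with phase means +/- SEM and a paired comparison over
completers — the analogue of the study's phenotype table.
"""

from common import parse_args
from ogttmet.pipeline import stage_indices


def main() -> None:
    args = parse_args(__doc__)
    _, summary = stage_indices(args.outdir)
    s = summary.set_index(["index", "phase"])
    for name in ("matsuda", "quicki", "homa", "fasting_glucose", "fasting_insulin"):
        pre = s.loc[(name, "pre")]
        post = s.loc[(name, "post")]
        print(f"{name:16s} pre {pre['mean']:8.3f} +/- {pre['sem']:.3f}   "
              f"post {post['mean']:8.3f} +/- {post['sem']:.3f}   "
              f"paired p {pre['paired_p']:.3g}")


if __name__ == "__main__":
    main()
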