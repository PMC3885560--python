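"""Incremental post-OGTT AUC excursions and responsiveness classes.

For every metabolite and phase: per-subject baseline-subtracted
trapezoid AUC, one-sample t against zero, and the four-way class from
the two phase-level flags (both / pre-only / post-only / neither).
"""

from common import parse_args
from ogttmet.pipeline import stage_auc


def main() -> None:
    args = parse_args(__doc__)
    _, excursions, classes = stage_auc(args.outdir)
    counts = classes["class"].value_counts()
    responsive = int(counts.get("both", 0) + counts.get("pre_only", 0)
                     + counts.get("post_only", 0))
    print(f"metabolites with nonzero excursion in at least one phase: {responsive}")
    for cls in ("both", "pre_only", "post_only", "neither"):
        print(f"  {cls:10s} {int(counts.get(cls, 0))}")
    neg = excursions[(excursions["phase"] == "pre") & excursions["nonzero"]
                     & (excursions["mean_auc"] < 0)]
    print(f"suppressed (negative-AUC) responders pre-intervention: {len(neg)}")


if __name__ == "__main__":
    main()
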