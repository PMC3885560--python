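"""Apply the reporting filter and sum normalization.

Metabolites present in at least half of all samples are retained; each
retained peak height is divided by its sample's total reported
intensity, putting every sample on a relative-abundance scale.
"""

import pandas as pd

from common import parse_args
from ogttmet.pipeline import stage_preprocess


def main() -> None:
    args = parse_args(__doc__)
    normalized = stage_preprocess(args.outdir)
    report = pd.read_csv(f"{args.outdir}/presence_report.tsv", sep="\t", comment="#")
    dropped = report[~report["retained"]]
    print(f"presence filter (>= 50% of {report['n_samples'].iloc[0]} samples): "
          f"retained {report['retained'].sum()} / {len(report)} metabolites")
    if len(dropped):
        print(f"dropped: {', '.join(dropped['metabolite_id'].head(10))}"
              + (" ..." if len(dropped) > 10 else ""))
    sums = normalized.groupby(["subject_id", "phase", "time_min"])["intensity"].sum()
    print(f"per-sample normalized sums: min {sums.min():.6f}, max {sums.max():.6f}")


if __name__ == "__main__":
    main()
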