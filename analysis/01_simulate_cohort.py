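"""Generate the synthetic study cohort.

Emulates the study design: 15 women enrolled pre-intervention, 12
completers re-tested post-intervention, pre-intervention OGTT series for
13 subjects, 321 plasma metabolites at 0/30/60/90/120 min, 20 planted
intervention-responsive metabolites (half fasting-level, half AUC), and
improved post-intervention insulin sensitivity.
"""

import pandas as pd

from common import parse_args
from ogttmet.pipeline import stage_simulate


def main() -> None:
    args = parse_args(__doc__)
    config = stage_simulate(args.outdir, seed=args.seed)
    truth = pd.read_csv(f"{args.outdir}/truth.tsv", sep="\t", comment="#")
    print(f"cohort: {config.n_subjects_pre} subjects pre / "
          f"{config.n_completers} completers post, "
          f"{config.n_metabolites} metabolites")
    print(f"planted responders: {len(truth)} "
          f"({(truth['channel'] == 'fasting').sum()} fasting-level, "
          f"{(truth['channel'] == 'auc').sum()} AUC)")
    print(f"artifacts in {args.outdir}/: panel.tsv subjects.tsv truth.tsv "
          "fingerprints.tsv")


if __name__ == "__main__":
    main()
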