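"""OGTT time-course PLS model and the chemical-similarity network.

Metabolite values are adjusted for the intervention (phase-specific
centering) and modeled against OGTT time; the LV1 loading of each
metabolite (sign = direction of change during the OGTT) decorates the
vertices of the Tanimoto > 0.7 similarity network.
"""

import numpy as np
import pandas as pd

from common import parse_args
from ogttmet.pipeline import stage_network, stage_timecourse


def main() -> None:
    args = parse_args(__doc__)
    model, scores, loadings = stage_timecourse(args.outdir)
    r = np.corrcoef(scores["lv1"], scores["time_min"])[0, 1]
    print(f"time model: A={model.n_components}, corr(LV1 score, time) = {r:.3f}")
    info = pd.read_csv(f"{args.outdir}/metabolite_info.tsv", sep="\t", comment="#")
    merged = info.merge(loadings.rename_axis("metabolite_id").reset_index())
    for arch, grp in merged.groupby("archetype"):
        print(f"  {arch:16s} mean LV1 loading {grp['loading_lv1'].mean():+.3f}")
    g = stage_network(args.outdir)
    comp = pd.read_csv(f"{args.outdir}/network_components.tsv", sep="\t", comment="#")
    print(f"network: {g.number_of_nodes()} vertices, {g.number_of_edges()} edges "
          f"(Tanimoto > 0.7), {len(comp)} connected components")


if __name__ == "__main__":
    main()
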