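"""Loading-prefiltered Spearman cross-correlation of phenotype and metabolites.

Only variables whose PLS-DA loading deviates from the mean loading by
more than one SD enter the panel; correlations with the Matsuda index
are listed per phase with the conventional star coding.
"""

from common import parse_args
from ogttmet.pipeline import stage_correlate


def main() -> None:
    args = parse_args(__doc__)
    pre, post = stage_correlate(args.outdir)
    for phase, tab in (("pre", pre), ("post", post)):
        mats = tab[((tab["var_a"] == "matsuda") | (tab["var_b"] == "matsuda"))
                   & (tab["stars"] != "")]
        print(f"{phase}: {len(tab)} variable pairs, "
              f"{len(mats)} significantly correlated with the Matsuda index")
        for _, r in mats.head(6).iterrows():
            other = r["var_b"] if r["var_a"] == "matsuda" else r["var_a"]
            print(f"  {other:24s} rho {r['rho']:+.3f}{r['stars']}  (n={r['n']})")


if __name__ == "__main__":
    main()
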