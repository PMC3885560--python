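"""Collate the analogues of the study's five result tables into report.json."""

import json

from common import parse_args
from ogttmet.pipeline import stage_report


def main() -> None:
    args = parse_args(__doc__)
    report = stage_report(args.outdir)
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
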