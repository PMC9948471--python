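"""Aggregate report: AAI network of the diverse population and section index."""

import json
from pathlib import Path

import pandas as pd

from _common import demo_config, parse_args
from longbin.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = demo_config(args.outdir, args.seed)
    run_pipeline(cfg, stages=["report"])
    out = Path(cfg.outdir)
    net = pd.read_csv(out / "aai_network.tsv", sep="\t")
    print("AAI / shared-protein network (parent vs strains of the diverse population):")
    print(net.to_string(index=False))
    report = json.loads((out / "report.json").read_text())
    print("\nreport sections:")
    for name, info in report["sections"].items():
        print(f"  {name}: {info['rows']} rows")


if __name__ == "__main__":
    main()
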