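"""Assembly QC: circularity evidence and marker completeness filters."""

from pathlib import Path

import pandas as pd

from _common import demo_config, parse_args
from longbin.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = demo_config(args.outdir, args.seed)
    run_pipeline(cfg, stages=["qc"])
    out = Path(cfg.outdir)
    circ = pd.read_csv(out / "qc_circularity.tsv", sep="\t")
    print("circularity verdicts (first {} genomes are truly circular):".format(
        cfg.community.n_circular))
    print(circ.to_string(index=False))
    print("\nmarker-set completeness/contamination filter:")
    print(pd.read_csv(out / "qc_markers.tsv", sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
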