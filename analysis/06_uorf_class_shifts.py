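#!/usr/bin/env python
"""uORF discovery and class-level TE aggregates.

Scans the 5'UTRs for AUG- and near-cognate-initiated uORFs, classifies their
Kozak contexts, and asks whether uORF-bearing transcript classes shift in
translation efficiency relative to the rest of the transcriptome in the
knockout contrast. Writes uorfs.tsv, uorf_class_shift.tsv, uorf_occupancy.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from riboprof.config import PipelineConfig
from riboprof.pipeline import run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results/analysis")
    args = parser.parse_args()

    cfg = PipelineConfig(output_dir=args.out, seed=args.seed)
    run_pipeline(cfg, ["uorf-shift"])
    out = Path(args.out)
    uorfs = pd.read_csv(out / "uorfs.tsv", sep="\t")
    shifts = pd.read_csv(out / "uorf_class_shift.tsv", sep="\t", index_col=0)
    print(f"discovered {len(uorfs)} uORFs on {uorfs['transcript_id'].nunique()} transcripts")
    print(uorfs["start_class"].value_counts().to_string())
    print("\nclass-level TE shifts (KO vs control):")
    print(shifts.to_string(float_format=lambda v: f"{v:.4f}"))
    print("\nno uORF-class effect was injected, so class shifts should sit near "
          "zero; isolated nominal p-values at these class sizes are chance findings")


if __name__ == "__main__":
    main()
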