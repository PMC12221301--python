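#!/usr/bin/env python
"""Differential translation efficiency: knockout vs control.

Runs the assay x genotype interaction Wald test on the DMSO arm after RPK
filtering, then counts significant genes at padj < 0.05 with |log2FC| >= 1
and checks them against the simulation's ground truth. Writes
te_results_ko.tsv and te_flagged_ko.tsv.
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

    cfg = PipelineConfig(output_dir=args.out, seed=args.seed, contrast="ko")
    run_pipeline(cfg, ["diffte"])
    out = Path(args.out)
    res = pd.read_csv(out / "te_results_ko.tsv", sep="\t", index_col=0)
    flagged = pd.read_csv(out / "te_flagged_ko.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(out / "truth.tsv", sep="\t", index_col=0)
    true_set = set(truth.index[truth["dlog2te_ko"] != 0])
    called = set(flagged.index)
    print(f"tested {len(res)} genes; {len(called)} called at padj<{cfg.alpha}, "
          f"|lfc|>={cfg.lfc_cut}")
    print(f"of the calls, {len(called & true_set)} carry a true injected TE shift "
          f"({len(true_set)} genes injected)")
    print("NOTE: at 3 replicates and dispersion 0.1 the per-gene test has little "
          "power against a 1-log2 shift; single-gene calls are expected to be sparse")


if __name__ == "__main__":
    main()
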