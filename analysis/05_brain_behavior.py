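#!/usr/bin/env python
"""Brain-behavior correlation and the strength-variability relation.

Generates cognitive scores from the cohort's score models (noisy linear
functions of connectivity summaries), correlates each chosen connection's
mean/variance with every score per group (Spearman, unadjusted), and
computes the Pearson relation between coupling strength <|DCCC|> and its
temporal variance across chosen connections — stronger couplings are
expected to fluctuate less. Writes results/correlations.csv and
results/mean_variance_relation.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fractalconn.presets import study_cohort
from fractalconn.stats_tools import abs_mean_variance_corr, spearman_table
from fractalconn.synthetic import gen_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summaries", type=Path, default=Path("results/summaries.csv"))
    ap.add_argument("--chosen", type=Path, default=Path("results/chosen_features.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    summaries = pd.read_csv(args.summaries, index_col=0)
    chosen = pd.read_csv(args.chosen)
    scores = gen_scores(summaries.drop(columns="group"), study_cohort(args.seed))
    scores.to_csv(args.out_dir / "scores.csv")

    feat_cols = [f"{stat}_dccc_{c1}_{c2}_s{s}"
                 for _, (c1, c2, s) in chosen.iterrows()
                 for stat in ("mu", "var")]
    table = spearman_table(summaries, scores, feat_cols)
    table.to_csv(args.out_dir / "correlations.csv", index=False)
    sig = table[table["p"] < 0.05]
    print(f"{len(sig)} of {len(table)} feature-score correlations at p < 0.05 "
          f"(unadjusted)")
    counts = sig.groupby(["group", "score"]).size()
    if len(counts):
        print(counts.to_string())

    pairs = [(f"mu_dccc_{c1}_{c2}_s{s}", f"var_dccc_{c1}_{c2}_s{s}")
             for _, (c1, c2, s) in chosen.iterrows()]
    mv = abs_mean_variance_corr(summaries, pairs)
    mv.to_csv(args.out_dir / "mean_variance_relation.csv", index=False)
    print("\nPearson r between <|DCCC|> and its temporal variance across "
          "chosen connections:")
    print(mv.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
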