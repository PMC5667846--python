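#!/usr/bin/env python
"""Normal-vs-abnormal screening ROC on a 70/30 split.

Trains the multiclass model on 70% of the data and scores the held-out
30% with 1 minus the normal-class score; reports AUC and the
Youden-index operating point (the cut-off granting balanced weight to
sensitivity and specificity).
"""

from pathlib import Path

import pandas as pd

from fundusml.experiments import ExperimentConfig, run_screening_roc
from fundusml.io import write_roc_points

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ExperimentConfig(n_per_class=100, dim=256, separation=2.0,
                           data_seed=0, split_seed=0)
    res = run_screening_roc(cfg)
    write_roc_points(res["roc"], RESULTS / "screening_roc_points.csv")
    summary = pd.DataFrame([{k: res[k] for k in
                             ("auc", "sensitivity", "specificity",
                              "youden_cutoff", "n_train", "n_test")}])
    summary.to_csv(RESULTS / "screening_roc_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nFinding: with {res['n_train']} training and {res['n_test']} "
          f"test samples the abnormality score reaches AUC {res['auc']:.3f}; "
          f"the Youden cut-off {res['youden_cutoff']:.3f} balances "
          f"sensitivity {res['sensitivity']:.3f} against specificity "
          f"{res['specificity']:.3f}.")


if __name__ == "__main__":
    main()
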