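#!/usr/bin/env python
"""Clinically motivated class-grouping scenarios.

Evaluates the four screening/staging groupings built around diabetic
retinopathy (DMR) and age-related macular degeneration (AMD): early
screening {normal, BDR, dry AMD}, the combined five-category setting,
DMR staging {normal, BDR, PDR}, and AMD staging {normal, dry AMD,
wet AMD}, each under stratified 5-fold cross-validation.
"""

from pathlib import Path

from fundusml.experiments import ExperimentConfig, run_scenarios

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ExperimentConfig(n_per_class=100, dim=256, separation=2.0,
                           data_seed=0, split_seed=0)
    df = run_scenarios(cfg)
    df.to_csv(RESULTS / "scenarios.csv", index=False)
    print(df.to_string(index=False))
    three = df[df.n_categories == 3].accuracy.mean()
    five = df[df.n_categories == 5].accuracy.iloc[0]
    print(f"\nFinding: three-category scenarios average accuracy "
          f"{three:.3f}; widening to the five-category DMR+AMD grouping "
          f"drops accuracy to {five:.3f}, mirroring the category-sweep "
          "dilution at a clinically meaningful granularity.")


if __name__ == "__main__":
    main()
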