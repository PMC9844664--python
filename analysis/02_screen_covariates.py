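"""Screen covariates against overall symptom severity.

Regresses the standardized total severity score (row sum of the 13 items)
on standardized candidate covariates and keeps those with p < 0.05; writes
results/covariate_regression.csv and prints the table.
"""

import argparse
from pathlib import Path

from symnet import overall_severity_regression
from symnet.dataset import SymptomDataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = SymptomDataset.from_csv(args.results / "data.csv")
    reg = overall_severity_regression(data)
    reg.table.to_csv(args.results / "covariate_regression.csv", index=False)
    print(reg.table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
    print(f"adjusted R^2 = {reg.r2_adj:.3f}, F = {reg.f_statistic:.2f}")
    print("selected covariates:", reg.selected)
    if reg.excluded:
        print("excluded (insufficient support):", reg.excluded)


if __name__ == "__main__":
    main()
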