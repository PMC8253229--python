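"""10-fold and leave-one-out cross-validation of the fitted models.

Uses the predictor sets stored by 04_fit_models.py and reports per-fold
and mean concordance (AUC) for both families; the two schemes should
agree closely when the models are stable.
"""

import argparse
from pathlib import Path

import pandas as pd

import canopywilt as cw

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indices", type=Path, default=ROOT / "results" / "indices.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cv_report.csv")
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--k", type=int, default=10)
    args = ap.parse_args()

    table = pd.read_csv(args.indices)
    rows = []
    for family in ("ordinal", "binary"):
        model = cw.load_model(ROOT / "results" / f"fitted_{family}.txt")
        predictors = list(model.coefficients)
        kf = cw.kfold_cv(table, family, k=args.k, seed=args.seed, predictors=predictors)
        loo = cw.loocv(table, family, predictors=predictors)
        print(f"{family}: 10-fold mean AUC {kf.mean_auc:.3f} "
              f"(folds {[round(a, 2) for a in kf.per_fold_auc]})")
        print(f"{family}: leave-one-out AUC {loo.mean_auc:.3f}")
        for fold, (n, auc) in enumerate(zip(kf.fold_sizes, kf.per_fold_auc), 1):
            rows.append({"family": family, "scheme": "kfold", "fold": fold,
                         "n": n, "auc": auc})
        rows.append({"family": family, "scheme": "loocv", "fold": 0,
                     "n": len(table), "auc": loo.mean_auc})
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"cross-validation report -> {args.out}")


if __name__ == "__main__":
    main()
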