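"""Fit the logistic signature on the candidate genes' expression and
validate it by leave-one-out cross-validation.

Reads results/{cohort,candidates.tsv}; writes results/signature_model.tsv
and results/loocv_predictions.tsv.
"""

from pathlib import Path

import pandas as pd

from cnax.classifier import fit_signature, loocv_accuracy
from cnax.synthetic import read_cohort

OUT = Path("results")


def main():
    cohort = read_cohort(OUT / "cohort")
    candidates = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    genes = [g for g in candidates["gene"] if g in cohort.expression.index]
    x = cohort.expression.loc[genes].T
    y = cohort.group_mask.astype(int)

    model = fit_signature(x, y)
    model.to_frame().to_csv(OUT / "signature_model.tsv", sep="\t", index=False)
    train_acc = 100.0 * (model.predict(x).to_numpy() == y).mean()
    acc, detail = loocv_accuracy(x, y)
    detail.to_csv(OUT / "loocv_predictions.tsv", sep="\t", index_label="sample")

    print(f"signature genes: {len(genes)}")
    print(f"training accuracy: {train_acc:.1f}%")
    print(f"LOOCV accuracy:    {acc:.1f}%")


if __name__ == "__main__":
    main()
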