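"""Survival validation of the signature classes: Kaplan-Meier 5-year
read-outs, log-rank comparison, and Cox regression of the predicted class.

Reads results/{cohort,loocv_predictions.tsv}; writes results/cox_class.tsv.
"""

from pathlib import Path

import pandas as pd

from cnax.survival import cox_fit, kaplan_meier, logrank_test
from cnax.synthetic import read_cohort

OUT = Path("results")


def main():
    cohort = read_cohort(OUT / "cohort")
    preds = pd.read_csv(OUT / "loocv_predictions.tsv", sep="\t", index_col="sample")
    ann = cohort.annotations.join(preds["predicted"])

    for label, cls in (("IBC-like", 1), ("nIBC-like", 0)):
        sub = ann[ann["predicted"] == cls]
        km = kaplan_meier(sub["time"], sub["event"])
        s, (lo, hi), flagged = km.survival_at(60.0)
        note = " (beyond follow-up)" if flagged else ""
        print(f"{label}: n={len(sub)}, 5-year survival {100 * s:.0f}% "
              f"[{100 * lo:.0f}-{100 * hi:.0f}]{note}")

    stat, p = logrank_test(ann["time"], ann["event"], ann["predicted"])
    print(f"log-rank: chi2={stat:.2f}, p={p:.2e}")

    cox = cox_fit(
        pd.DataFrame({"time": ann["time"], "event": ann["event"],
                      "ibc_like": ann["predicted"]}),
        ["ibc_like"],
    )
    cox.to_csv(OUT / "cox_class.tsv", sep="\t", index=False)
    r = cox.iloc[0]
    print(f"Cox HR (IBC-like vs nIBC-like): {r['hr']:.2f} "
          f"[{r['ci_low']:.2f}-{r['ci_high']:.2f}], p={r['p']:.2e}")


if __name__ == "__main__":
    main()
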