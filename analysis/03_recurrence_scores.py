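"""Score per-probe CNA recurrence (frequency x amplitude with a
within-sample permutation null) separately per group and direction, and
extract the significant recurrent regions.

Reads results/{cohort,smoothed.tsv,cna_calls.tsv}; writes
results/recurrent_regions.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from cnax.recurrence import gistic_scores, significant_regions
from cnax.synthetic import read_cohort

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    cohort = read_cohort(OUT / "cohort")
    smoothed = pd.read_csv(OUT / "smoothed.tsv", sep="\t", index_col="probe_id").T
    states = pd.read_csv(OUT / "cna_calls.tsv", sep="\t", index_col="probe_id").T
    mask = cohort.group_mask

    rows = []
    for grp, m in (("A", mask), ("B", ~mask)):
        for direction in ("gain", "loss"):
            gs = gistic_scores(smoothed.loc[m], states.loc[m], direction,
                               n_boot=1000, seed=SEED)
            for r in significant_regions(gs, cohort.probes, cohort.gene_map):
                rows.append({
                    "group": grp, "chrom": r.chrom, "start": r.start, "end": r.end,
                    "direction": r.direction, "peak_score": r.peak_score,
                    "frequency": r.frequency, "n_probes": r.n_probes,
                    "n_genes": len(r.genes),
                })
    regions = pd.DataFrame(rows, columns=["group", "chrom", "start", "end", "direction",
                                          "peak_score", "frequency", "n_probes", "n_genes"])
    regions.to_csv(OUT / "recurrent_regions.tsv", sep="\t", index=False)
    print("significant recurrent regions per group/direction:")
    if regions.empty:
        print("(none)")
    else:
        print(regions.groupby(["group", "direction"]).size().to_string())


if __name__ == "__main__":
    main()
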