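"""Screen every gene for CNA frequencies that differ between the two
groups (Fisher exact per gene, BH-FDR across genes, gains and losses).

Reads results/{cohort,cna_calls.tsv}; writes results/differential_cna.tsv.
"""

from pathlib import Path

import pandas as pd

from cnax.pipeline import asdict_result
from cnax.stats import differential_cna
from cnax.synthetic import read_cohort

OUT = Path("results")


def main():
    cohort = read_cohort(OUT / "cohort")
    states = pd.read_csv(OUT / "cna_calls.tsv", sep="\t", index_col="probe_id").T
    mask = cohort.group_mask

    results = []
    for level in ("gain", "loss"):
        results += differential_cna(states, cohort.gene_map, mask, level=level)
    table = pd.DataFrame([asdict_result(r) for r in results])
    table.to_csv(OUT / "differential_cna.tsv", sep="\t", index=False)

    print(f"genes with differential CNA frequency (q < 0.05): {len(table)}")
    if not table.empty:
        print(table.groupby(["direction", "associated_group"]).size().to_string())


if __name__ == "__main__":
    main()
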