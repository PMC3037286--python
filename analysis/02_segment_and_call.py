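"""Segment every genome track (CBS), call CNA states, classify genome
patterns, and summarize per-sample alteration burden.

Reads results/cohort/, writes segments.seg, smoothed.tsv, cna_calls.tsv and
annotations_with_patterns.tsv under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from cnax import calling, segmentation
from cnax.synthetic import read_cohort

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_PERM = 128  # permutation budget per split test; see docs/methods.md


def main():
    cohort = read_cohort(OUT / "cohort")
    smoothed, seg_map = segmentation.segment_cohort(
        cohort.probes, cohort.genome, n_perm=N_PERM, seed=SEED
    )
    segmentation.segments_to_frame(seg_map).to_csv(OUT / "segments.seg", sep="\t", index=False)
    smoothed.T.to_csv(OUT / "smoothed.tsv", sep="\t", index_label="probe_id")

    params = calling.CnaCallParams()
    states = pd.DataFrame(
        calling.call_cna(smoothed.to_numpy(), params),
        index=smoothed.index, columns=smoothed.columns,
    )
    states.T.to_csv(OUT / "cna_calls.tsv", sep="\t", index_label="probe_id")

    ann = cohort.annotations.copy()
    ann["genomic_pattern"] = [
        calling.classify_pattern(seg_map[s], states.loc[s].to_numpy(), params).value
        for s in cohort.samples
    ]
    ann["altered_pct"] = [
        calling.altered_fraction(states.loc[s].to_numpy()) for s in cohort.samples
    ]
    ann.to_csv(OUT / "annotations_with_patterns.tsv", sep="\t", index_label="sample")

    by_group = ann.groupby("group")["altered_pct"].median()
    print(f"segments: {sum(len(v) for v in seg_map.values())} across {len(seg_map)} samples")
    print("median altered probes per sample (%):")
    print(by_group.round(2).to_string())
    print("genomic patterns by group:")
    print(ann.groupby(["group", "genomic_pattern"]).size().to_string())


if __name__ == "__main__":
    main()
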