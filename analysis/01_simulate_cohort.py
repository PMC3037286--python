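"""Generate the reference synthetic cohort and write it to results/cohort/.

Conditions: 49 group-A (IBC-like) + 124 group-B samples, 3,000 aCGH probes
over 15 chromosomes, 5,000 genes, 24 group-A-specific dosage-coupled
planted gains in 8 regions, plus shared gains and a group-B loss that the
downstream screens must reject.
"""

import sys
from pathlib import Path

from cnax.synthetic import default_cohort_config, generate_cohort, write_cohort

OUT = Path("results/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    cfg = default_cohort_config(seed=SEED)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, OUT)
    n_planted = sum(
        len(a.genes) for a in cfg.planted if a.dosage_coupled and a.direction == "gain"
    )
    print(f"cohort: {cohort.genome.shape[0]} samples x {cohort.genome.shape[1]} probes, "
          f"{cohort.expression.shape[0]} genes")
    print(f"planted group-A dosage-coupled gain genes: {n_planted}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
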