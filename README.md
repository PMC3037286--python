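# cnax — integrated aCGH + expression comparative analysis

`cnax` is a tested re-implementation of a classic integrated tumor-genomics
workflow: contrasting two clinical groups of breast tumors — inflammatory
breast cancer (IBC) versus non-inflammatory (nIBC) — from probe-level
array-CGH log2 ratios and gene-expression microarrays through to a
prognostic gene signature. It is aimed at anyone who wants the full chain
of that analysis as importable, unit-tested building blocks rather than a
one-off collection of R scripts:

1. **Segmentation** — circular binary segmentation (CBS) of each sample's
   log2-ratio track into constant-copy-number segments (≥ 5 consecutive
   probes per segment); each probe inherits its segment mean ("smoothed"
   value).
2. **CNA calling** — thresholds on |smoothed log2 ratio|: > 0.5 for
   low-level gain/loss (±1), > 1.0 for amplification/deletion (±2);
   per-sample alteration burden and genome-pattern classes (*simplex*,
   *complex sawtooth*, *complex firestorm*).
3. **Recurrence scoring** — a GISTIC-style per-probe score
   *f × ā* (alteration frequency × mean amplitude among altered samples)
   with a within-sample permutation null, merged into significant regions
   and recurrently altered genes.
4. **Differential screen** — per-gene Fisher exact tests of alteration
   frequency between groups with Benjamini–Hochberg FDR control
   (the Freeman–Halton exact extension handles r×c annotation tables).
5. **Integration** — the three-criterion candidate-gene filter over the
   differential genes: (i) combined-event (gain + overexpression)
   frequencies differ between groups, (ii) expression tracks copy number
   (Student t, FDR), (iii) expression differs between groups;
   overexpression means log2(sample) − log2(normal pool) ≥ 1.
6. **Classification** — a logistic signature over the candidate genes,
   score = β₀ + Σ βg·xg, thresholded at 0 into "IBC-like" vs "nIBC-like";
   validated by leave-one-out cross-validation and applicable to external
   cohorts (probes collapsed per gene by highest within-dataset variance).
7. **Survival** — Kaplan–Meier curves with Greenwood bands (5-year DFS at
   60 months), log-rank tests, and Cox proportional-hazards regression
   (Efron ties, Wald inference).

Because the original tumor cohort is not bundled, the package ships a
**synthetic-cohort generator** (`cnax.synthetic`) that emulates the data's
statistical structure — segmental log2 profiles with probe noise, planted
recurrent alterations with group-biased carrier frequencies, dosage-driven
expression for coupled genes, clinically structured annotations, and
proportional-hazards survival — with a full ground-truth record, so every
stage is verifiable by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
reference synthetic cohort (49 + 124 samples, 3,000 probes, 5,000 genes,
24 planted group-A-specific dosage-coupled gains):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_segment_and_call.py
python analysis/03_recurrence_scores.py
python analysis/04_differential_screen.py
python analysis/05_integrate_candidates.py
python analysis/06_fit_classifier.py
python analysis/07_survival_analysis.py
```

Output of the run at seed 1 (abridged):

```
median altered probes per sample (%):
A    2.0
B    0.8
genes with differential CNA frequency (q < 0.05): 206
candidate genes: 24
planted truth recovered: 24/24
false positives: none
signature genes: 24
training accuracy: 99.4%
LOOCV accuracy:    87.3%
IBC-like: n=51, 5-year survival 53% [37-67]
nIBC-like: n=122, 5-year survival 75% [66-82]
log-rank: chi2=10.59, p=1.14e-03
Cox HR (IBC-like vs nIBC-like): 2.17 [1.35-3.51], p=1.49e-03
```

Reading it: group A carries roughly twice the alteration burden of group
B; the differential screen flags the genes inside planted (and bystander)
regions; the three-criterion integration filter narrows those 206 genes to
exactly the 24 planted dosage-coupled gains; the logistic signature built
on them separates the groups at 87% leave-one-out accuracy; and the
signature classes split survival (IBC-like tumors relapse faster), exactly
the qualitative behavior expected of the original analysis.

The same chain is available as a library call
(`cnax.pipeline.run_pipeline` / `analyze_cohort`) and as a CLI
(`cnax run-all`, `cnax simulate`, …). Real cohorts enter through the same
TSV formats the generator writes (`cnax.synthetic.read_cohort`).

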