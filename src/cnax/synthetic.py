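"""Synthetic paired aCGH + expression cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
per-sample genome tracks are sums of planted recurrent alterations
(drawn per group with group-specific carrier probabilities), sub-threshold
random background segments, and i.i.d. probe noise; expression of
dosage-coupled genes shifts with the carried copy-number amplitude;
annotations (grade, IHC ER/ERBB2/P53, subtype) follow group-dependent
frequencies modeled on a two-group breast-cancer cohort; survival times
come from an exponential proportional-hazards model on the group label
with uniform censoring. Every planted event is recorded in a truth table
so parameter recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlantedAlteration",
    "SurvivalParams",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "simulate_survival",
    "default_cohort_config",
]

MIN_PLANTED_WIDTH = 5  # a narrower event cannot survive min-width segmentation

# Group-conditional annotation frequencies (group A = IBC-like arm of the
# contrast, group B = the control arm).
GRADE_PROBS = {"A": (0.00, 0.17, 0.83), "B": (0.24, 0.47, 0.29)}
ER_POS = {"A": 0.48, "B": 0.68}
ERBB2_POS = {"A": 0.39, "B": 0.12}
P53_POS = {"A": 0.65, "B": 0.34}
SUBTYPES = ("basal", "ERBB2", "luminal A", "luminal B", "normal")
SUBTYPE_PROBS = {"A": (0.21, 0.21, 0.14, 0.24, 0.21), "B": (0.19, 0.07, 0.47, 0.13, 0.13)}


@dataclass(frozen=True)
class PlantedAlteration:
    """A recurrent gain or loss planted over a contiguous probe interval.

    ``genes`` maps each member gene to its own (global, half-open) probe
    interval inside the region; only ``dosage_coupled`` alterations shift
    the expression of their genes in carriers. ``amplitude`` is the signed
    log2 shift added to carrier tracks and must match ``direction``.
    """

    name: str
    start_probe: int
    end_probe: int
    direction: str              # "gain" | "loss"
    amplitude: float
    freq_a: float
    freq_b: float
    genes: dict = field(default_factory=dict)
    dosage_coupled: bool = True

    def validate(self, n_probes: int) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"{self.name}: direction must be gain or loss")
        if self.direction == "gain" and self.amplitude <= 0:
            raise ValueError(f"{self.name}: gain amplitude must be positive")
        if self.direction == "loss" and self.amplitude >= 0:
            raise ValueError(f"{self.name}: loss amplitude must be negative")
        if not (0 <= self.freq_a <= 1 and 0 <= self.freq_b <= 1):
            raise ValueError(f"{self.name}: carrier frequencies must lie in [0, 1]")
        if not (0 <= self.start_probe < self.end_probe <= n_probes):
            raise ValueError(f"{self.name}: probe interval out of range")
        if self.end_probe - self.start_probe < MIN_PLANTED_WIDTH:
            raise ValueError(
                f"{self.name}: planted interval has "
                f"{self.end_probe - self.start_probe} probes, fewer than "
                f"{MIN_PLANTED_WIDTH}; it could not survive segmentation"
            )
        for g, (s, e) in self.genes.items():
            if not (self.start_probe <= s < e <= self.end_probe):
                raise ValueError(f"{self.name}: gene {g} interval outside the region")
            if e - s < MIN_PLANTED_WIDTH:
                raise ValueError(
                    f"{self.name}: gene {g} spans {e - s} probes (< {MIN_PLANTED_WIDTH})"
                )


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential baseline with a proportional hazard on the group label.

    ``baseline_hazard`` is events per month in group B; group A hazard is
    baseline * exp(log_hr). Censoring times are uniform on
    (0, censor_upper] months.
    """

    baseline_hazard: float = 0.0037
    log_hr: float = 1.49
    censor_upper: float = 180.0


@dataclass(frozen=True)
class CohortConfig:
    n_group_a: int = 49
    n_group_b: int = 124
    n_chrom: int = 15
    probes_per_chrom: int = 200
    probe_spacing_bp: int = 500_000
    n_genes: int = 5000
    probe_noise_sd: float = 0.15
    segment_rate: float = 0.5           # expected background segments / chrom / sample
    background_sd: float = 0.3          # N(0, sd) truncated to |a| < 0.5
    planted: tuple = ()
    dosage_slope: float = 1.1           # expression log2 per copy-number log2
    expression_noise_sd: float = 0.4
    floor_offset: float = 256.0         # linear-scale baseline (log2 = 8)
    baseline_log2_sd: float = 1.0
    survival: SurvivalParams = SurvivalParams()
    seed: int = 0

    @property
    def n_probes(self) -> int:
        return self.n_chrom * self.probes_per_chrom

    def validate(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_chrom", "probes_per_chrom", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("probe_noise_sd", "expression_noise_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.segment_rate < 0:
            raise ValueError("segment_rate must be non-negative")
        for alt in self.planted:
            alt.validate(self.n_probes)
            c0 = alt.start_probe // self.probes_per_chrom
            c1 = (alt.end_probe - 1) // self.probes_per_chrom
            if c0 != c1:
                raise ValueError(f"{alt.name}: interval crosses a chromosome boundary")


@dataclass
class Cohort:
    """Paired genome/expression matrices with annotations and truth.

    genome: samples x probes log2 ratios; expression: genes x samples log2;
    normal_pool: per-gene log2 reference; truth: samples x planted
    alterations (carrier flags).
    """

    probes: pd.DataFrame          # probe_id, chrom, start, end
    genome: pd.DataFrame
    gene_map: pd.DataFrame        # gene, chrom, start_probe, end_probe, probeset
    expression: pd.DataFrame
    normal_pool: pd.Series
    annotations: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    @property
    def samples(self) -> list[str]:
        return list(self.genome.index)

    @property
    def group_mask(self) -> np.ndarray:
        return (self.annotations["group"] == "A").to_numpy()


def _probe_table(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chrom):
        for i in range(config.probes_per_chrom):
            idx = c * config.probes_per_chrom + i
            start = i * config.probe_spacing_bp
            rows.append(
                {
                    "probe_id": f"P{idx:06d}",
                    "chrom": f"chr{c + 1}",
                    "start": start,
                    "end": start + 1000,
                }
            )
    return pd.DataFrame(rows)


def _gene_table(config: CohortConfig) -> pd.DataFrame:
    """Tile genes along the genome; planted genes get their declared
    intervals."""
    planted_intervals = {
        g: (s, e) for alt in config.planted for g, (s, e) in alt.genes.items()
    }
    rows = []
    for i in range(config.n_genes):
        gene = f"G{i:04d}"
        if gene in planted_intervals:
            s, e = planted_intervals[gene]
        else:
            s = int(i * config.n_probes / config.n_genes)
            e = min(s + 1, config.n_probes)
        chrom = f"chr{s // config.probes_per_chrom + 1}"
        rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "start_probe": s,
                "end_probe": e,
                "probeset": f"{10000 + i}_at",
            }
        )
    return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    while True:
        a = rng.normal(0.0, sd)
        if abs(a) < bound:
            return float(a)


def simulate_survival(
    is_group_a: np.ndarray, params: SurvivalParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) under the exponential PH model with uniform
    censoring."""
    is_group_a = np.asarray(is_group_a, dtype=bool)
    hazard = params.baseline_hazard * np.exp(params.log_hr * is_group_a)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(0.0, params.censor_upper, size=len(t))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic cohort from the config's seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_group_a + config.n_group_b
    samples = [f"S{i:03d}" for i in range(n)]
    groups = np.array(["A"] * config.n_group_a + ["B"] * config.n_group_b)
    probes = _probe_table(config)
    gene_map = _gene_table(config)

    # carriers per alteration x sample
    truth = {}
    for alt in config.planted:
        freq = np.where(groups == "A", alt.freq_a, alt.freq_b)
        truth[alt.name] = rng.random(n) < freq
    truth_df = pd.DataFrame(truth, index=samples, dtype=bool)

    genome = np.zeros((n, config.n_probes))
    for s in range(n):
        for c in range(config.n_chrom):
            k = rng.poisson(config.segment_rate)
            lo = c * config.probes_per_chrom
            hi = lo + config.probes_per_chrom
            for _ in range(k):
                a, b = np.sort(rng.integers(lo, hi, size=2))
                if a == b:
                    continue
                genome[s, a:b] += _truncated_normal(rng, config.background_sd, 0.5)
        for alt in config.planted:
            if truth_df.iloc[s][alt.name]:
                genome[s, alt.start_probe : alt.end_probe] += alt.amplitude
    if config.probe_noise_sd > 0:
        genome += rng.normal(0.0, config.probe_noise_sd, size=genome.shape)
    genome_df = pd.DataFrame(genome, index=samples, columns=list(probes["probe_id"]))

    # expression: per-gene baseline; dosage-coupled genes shift in carriers
    base_mean = float(np.log2(config.floor_offset))
    baseline = base_mean + rng.normal(0.0, config.baseline_log2_sd, size=config.n_genes)
    planted_gene_idx = {}
    for alt in config.planted:
        for g in alt.genes:
            planted_gene_idx[g] = int(g[1:])
    for g, i in planted_gene_idx.items():
        baseline[i] = base_mean + 0.5 + rng.normal(0.0, 0.3)  # safely above the floor
    expr = np.tile(baseline[:, None], (1, n))
    for alt in config.planted:
        if not alt.dosage_coupled:
            continue
        carriers = truth_df[alt.name].to_numpy()
        for g in alt.genes:
            expr[int(g[1:]), carriers] += config.dosage_slope * alt.amplitude
    if config.expression_noise_sd > 0:
        expr += rng.normal(0.0, config.expression_noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=list(gene_map["gene"]), columns=samples)
    expression.index.name = "gene"
    normal_pool = pd.Series(baseline, index=expression.index, name="normal_pool")

    # annotations
    def draw_cat(options, probs_by_group):
        out = np.empty(n, dtype=object)
        for g in ("A", "B"):
            m = groups == g
            p = np.asarray(probs_by_group[g], dtype=float)
            p = p / p.sum()
            out[m] = rng.choice(options, size=int(m.sum()), p=p)
        return out

    def draw_pos(prob_by_group):
        r = rng.random(n)
        thr = np.where(groups == "A", prob_by_group["A"], prob_by_group["B"])
        return np.where(r < thr, "positive", "negative")

    grade = draw_cat([1, 2, 3], GRADE_PROBS).astype(int)
    er = draw_pos(ER_POS)
    erbb2 = draw_pos(ERBB2_POS)
    p53 = draw_pos(P53_POS)
    subtype = draw_cat(list(SUBTYPES), SUBTYPE_PROBS)
    time, event = simulate_survival(groups == "A", config.survival, rng)
    annotations = pd.DataFrame(
        {
            "group": groups,
            "grade": grade,
            "er": er,
            "erbb2": erbb2,
            "p53": p53,
            "subtype": subtype,
            "time": time,
            "event": event,
        },
        index=samples,
    )
    annotations.index.name = "sample"
    genome_df.index.name = "sample"
    truth_df.index.name = "sample"
    return Cohort(
        probes=probes,
        genome=genome_df,
        gene_map=gene_map,
        expression=expression,
        normal_pool=normal_pool,
        annotations=annotations,
        truth=truth_df,
        config=config,
    )


# ---------------------------------------------------------------------------
# I/O: plain TSV files plus a JSON config, round-trip exact.

ANNOTATION_COLUMNS = ["group", "grade", "er", "erbb2", "p53", "subtype", "time", "event"]


def write_cohort(cohort: Cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    genome = pd.concat(
        [cohort.probes.reset_index(drop=True), cohort.genome.T.reset_index(drop=True)], axis=1
    )
    genome.columns = list(cohort.probes.columns) + cohort.samples
    genome.to_csv(d / "genome.tsv", sep="\t", index=False)
    cohort.expression.to_csv(d / "expression.tsv", sep="\t", index_label="gene")
    cohort.normal_pool.to_frame().to_csv(d / "normal_pool.tsv", sep="\t", index_label="gene")
    cohort.annotations.to_csv(d / "annotations.tsv", sep="\t", index_label="sample")
    cohort.gene_map.to_csv(d / "gene_map.tsv", sep="\t", index=False)
    cohort.truth.to_csv(d / "truth.tsv", sep="\t", index_label="sample")
    cfg = asdict(cohort.config)
    cfg["planted"] = [asdict(a) for a in cohort.config.planted]
    (d / "config.json").write_text(json.dumps(cfg, indent=1))


def _parse_config(raw: dict) -> CohortConfig:
    planted = tuple(
        PlantedAlteration(
            **{**a, "genes": {g: tuple(v) for g, v in a.get("genes", {}).items()}}
        )
        for a in raw.pop("planted", [])
    )
    surv = SurvivalParams(**raw.pop("survival"))
    return CohortConfig(planted=planted, survival=surv, **raw)


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    try:
        genome_raw = pd.read_csv(d / "genome.tsv", sep="\t")
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise ValueError(f"malformed genome file: {exc}") from exc
    probe_cols = ["probe_id", "chrom", "start", "end"]
    missing = [c for c in probe_cols if c not in genome_raw.columns]
    if missing:
        raise ValueError(f"genome file missing columns: {missing}")
    for c, sub in genome_raw.groupby("chrom", sort=False):
        if np.any(np.diff(sub["start"].to_numpy()) < 0):
            raise ValueError(f"genome probes on {c} are not sorted by position")
    probes = genome_raw[probe_cols].copy()
    sample_cols = [c for c in genome_raw.columns if c not in probe_cols]
    genome = genome_raw[sample_cols].T
    genome.columns = list(probes["probe_id"])
    genome = genome.astype(float)
    genome.index.name = "sample"
    genome.columns.name = None

    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col="gene")
    normal_pool = pd.read_csv(d / "normal_pool.tsv", sep="\t", index_col="gene")["normal_pool"]
    annotations = pd.read_csv(d / "annotations.tsv", sep="\t", index_col="sample")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotations file missing required columns: {missing}")
    gene_map = pd.read_csv(d / "gene_map.tsv", sep="\t")
    truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col="sample").astype(bool)
    config = _parse_config(json.loads((d / "config.json").read_text()))
    if len(annotations) != genome.shape[0] or expression.shape[1] != genome.shape[0]:
        raise ValueError("matrix dimensions inconsistent with annotations")
    return Cohort(
        probes=probes,
        genome=genome,
        gene_map=gene_map,
        expression=expression,
        normal_pool=normal_pool,
        annotations=annotations,
        truth=truth,
        config=config,
    )


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The reference study conditions: 49 + 124 samples, 5,000 genes,
    3,000 probes over 15 chromosomes, and 24 group-A-specific
    dosage-coupled planted gains (8 regions x 3 genes, mixing low-level
    gains and high-level amplifications), plus shared and loss events that
    the comparative screens must reject."""
    planted = []
    gene_counter = 0

    def region(chrom_idx, amplitude, freq_a, freq_b, n_coupled, direction="gain",
               coupled=True, name=None):
        nonlocal gene_counter
        lo = chrom_idx * 200 + 80
        hi = lo + 12
        genes = {}
        for k in range(n_coupled):
            gi = chrom_idx * 333 + 100 + k  # a gene index tiled near the region
            genes[f"G{gene_counter + k:04d}"] = (lo + 3 * k, lo + 3 * k + 6)
        gene_counter += n_coupled
        planted.append(
            PlantedAlteration(
                name=name or f"{direction}_{chrom_idx + 1}",
                start_probe=lo,
                end_probe=hi,
                direction=direction,
                amplitude=amplitude,
                freq_a=freq_a,
                freq_b=freq_b,
                genes=genes,
                dosage_coupled=coupled,
            )
        )

    # 24 IBC-specific dosage-coupled gains: 8 regions x 3 genes
    for c in range(8):
        amp = 0.9 if c % 2 == 0 else 1.5
        region(c, amplitude=amp, freq_a=0.55, freq_b=0.04, n_coupled=3)
    # events both screens must reject: shared gains, an uncoupled
    # group-B-associated loss
    region(8, amplitude=0.8, freq_a=0.30, freq_b=0.30, n_coupled=2, coupled=False,
           name="shared_gain_9")
    region(9, amplitude=0.8, freq_a=0.30, freq_b=0.30, n_coupled=2, coupled=False,
           name="shared_gain_10")
    region(10, amplitude=-0.9, freq_a=0.05, freq_b=0.25, n_coupled=2,
           direction="loss", coupled=False, name="b_loss_11")
    # an explicit planted override (e.g. an event-free null cohort) wins
    planted_out = overrides.pop("planted", tuple(planted))
    return CohortConfig(planted=planted_out, seed=seed, **overrides)
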