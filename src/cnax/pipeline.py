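"""End-to-end pipeline: orchestrates segmentation, calling, recurrence
scoring, differential screening, expression preprocessing, integration,
classification, and survival analysis with a structured config and a
deterministic output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, classifier, integration, recurrence, segmentation, stats, survival
from .synthetic import Cohort, CohortConfig, PlantedAlteration, generate_cohort, read_cohort

logger = logging.getLogger("cnax")

__all__ = ["PipelineConfig", "run_pipeline", "demo_fixture"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the published operating point
    (CNA thresholds 0.5/1.0, expression floor 100, q and p cutoffs 0.05,
    min 2 altered samples, min segment width 5 probes)."""

    cohort_dir: str | None = None        # read a written cohort; None = simulate
    out_dir: str = "results/pipeline"
    seed: int = 0
    # segmentation
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    min_width: int = 5
    # calling
    low_threshold: float = 0.5
    high_threshold: float = 1.0
    # recurrence
    gistic_n_boot: int = 1000
    gistic_alpha: float = 0.05
    # screens
    q_cut: float = 0.05
    p_cut: float = 0.05
    min_altered: int = 2
    # expression
    floor: float = 100.0
    top_k: int | None = None
    # classifier
    ridge: float = 1e-3
    # stage toggles
    run_recurrence: bool = True
    run_survival: bool = True
    run_loocv: bool = True

    def validate(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be below high_threshold")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if not (0 < self.cbs_alpha < 1 and 0 < self.q_cut < 1 and 0 < self.p_cut < 1):
            raise ValueError("significance cutoffs must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute every enabled stage in order and write a manifest.

    Returns the manifest dict (stage outputs, file hashes, headline
    numbers). With a fixed seed the manifest is bit-identical between runs.
    A stage failure aborts with the stage name; files already written are
    left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    files: list[Path] = []

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage("cohort")
        if cohort is None:
            if config.cohort_dir is not None:
                cohort = read_cohort(config.cohort_dir)
            else:
                cohort = generate_cohort(demo_fixture_config(seed=config.seed))
        group_mask = cohort.group_mask

        stage("segment")
        smoothed, seg_map = segmentation.segment_cohort(
            cohort.probes,
            cohort.genome,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            min_width=config.min_width,
            seed=config.seed,
        )
        files.append(_write(segmentation.segments_to_frame(seg_map), out / "segments.seg", index=False))

        stage("call")
        params = calling.CnaCallParams(config.low_threshold, config.high_threshold)
        states = pd.DataFrame(
            calling.call_cna(smoothed.to_numpy(), params),
            index=smoothed.index,
            columns=smoothed.columns,
        )
        files.append(_write(states.T, out / "cna_calls.tsv", index_label="probe_id"))
        patterns = pd.Series(
            {
                s: calling.classify_pattern(seg_map[s], states.loc[s].to_numpy(), params).value
                for s in cohort.samples
            },
            name="genomic_pattern",
        )
        burden = pd.Series(
            {s: calling.altered_fraction(states.loc[s].to_numpy()) for s in cohort.samples},
            name="altered_pct",
        )
        ann = cohort.annotations.copy()
        ann["genomic_pattern"] = patterns
        ann["altered_pct"] = burden
        files.append(_write(ann, out / "annotations_with_patterns.tsv", index_label="sample"))
        for grp, m in (("A", group_mask), ("B", ~group_mask)):
            files.append(
                _write(
                    calling.group_frequencies(states, m),
                    out / f"frequencies_group{grp}.tsv",
                    index_label="probe_id",
                )
            )

        if config.run_recurrence:
            stage("score")
            region_rows = []
            for grp, m in (("A", group_mask), ("B", ~group_mask)):
                sub_sm = smoothed.loc[m]
                sub_st = states.loc[m]
                for direction in ("gain", "loss"):
                    gs = recurrence.gistic_scores(
                        sub_sm, sub_st, direction, n_boot=config.gistic_n_boot, seed=config.seed
                    )
                    for r in recurrence.significant_regions(
                        gs, cohort.probes, cohort.gene_map, alpha=config.gistic_alpha
                    ):
                        region_rows.append(
                            {
                                "group": grp,
                                "chrom": r.chrom,
                                "start": r.start,
                                "end": r.end,
                                "direction": r.direction,
                                "peak_score": r.peak_score,
                                "frequency": r.frequency,
                                "n_probes": r.n_probes,
                                "genes": ",".join(map(str, r.genes)),
                            }
                        )
            files.append(
                _write(
                    pd.DataFrame(
                        region_rows,
                        columns=["group", "chrom", "start", "end", "direction",
                                 "peak_score", "frequency", "n_probes", "genes"],
                    ),
                    out / "recurrent_regions.tsv",
                    index=False,
                )
            )

        stage("differential")
        differential = []
        for level in ("gain", "loss"):
            differential += stats.differential_cna(
                states,
                cohort.gene_map,
                group_mask,
                level=level,
                q_cut=config.q_cut,
                min_altered=config.min_altered,
            )
        files.append(
            _write(
                pd.DataFrame([asdict_result(r) for r in differential]),
                out / "differential_cna.tsv",
                index=False,
            )
        )

        stage("expression")
        from .expression import floor_filter, variance_filter

        expr = floor_filter(cohort.expression, floor=config.floor)
        if config.top_k:
            expr = variance_filter(expr, config.top_k)

        stage("integrate")
        candidates = integration.candidate_filter(
            differential,
            states,
            cohort.gene_map,
            expr,
            cohort.normal_pool,
            group_mask,
            p_cut=config.p_cut,
            q_cut=config.q_cut,
            min_altered=config.min_altered,
        )
        cand_df = pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "direction": c.direction,
                    "combined_a": c.combined_a,
                    "n_a": c.n_a,
                    "combined_b": c.combined_b,
                    "n_b": c.n_b,
                    "p_combined": c.p_combined,
                    "q_dosage": c.q_dosage,
                    "p_expression": c.p_expression,
                }
                for c in candidates
            ],
            columns=["gene", "direction", "combined_a", "n_a", "combined_b", "n_b",
                     "p_combined", "q_dosage", "p_expression"],
        )
        files.append(_write(cand_df, out / "candidates.tsv", index=False))
        manifest["n_candidates"] = len(candidates)

        stage("classify")
        loocv_acc = None
        if candidates and config.run_loocv:
            genes = [c.gene for c in candidates]
            x = expr.loc[[g for g in genes if g in expr.index]].T
            y = group_mask.astype(int)
            model = classifier.fit_signature(x, y, ridge=config.ridge)
            files.append(_write(model.to_frame(), out / "signature_model.tsv", index=False))
            loocv_acc, detail = classifier.loocv_accuracy(x, y, ridge=config.ridge)
            files.append(_write(detail, out / "loocv_predictions.tsv", index_label="sample"))
            manifest["loocv_accuracy_pct"] = loocv_acc

        if config.run_survival:
            stage("survival")
            ann2 = cohort.annotations
            stat, p = survival.logrank_test(
                ann2["time"], ann2["event"], (ann2["group"] == "A").astype(int)
            )
            cox_df = survival.cox_fit(
                pd.DataFrame(
                    {
                        "time": ann2["time"],
                        "event": ann2["event"],
                        "group_a": (ann2["group"] == "A").astype(int),
                    }
                ),
                ["group_a"],
            )
            files.append(_write(cox_df, out / "cox_group.tsv", index=False))
            manifest["logrank_p"] = p
            manifest["cox_hr_group"] = float(cox_df.loc[0, "hr"])
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if v == "ok"]
        raise RuntimeError(
            f"pipeline failed in stage {failed[-1] if failed else '?'!r}: {exc}"
        ) from exc

    for f in files:
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def asdict_result(r) -> dict:
    return {
        "gene": r.gene,
        "direction": r.direction,
        "altered_a": r.altered_a,
        "n_a": r.n_a,
        "altered_b": r.altered_b,
        "n_b": r.n_b,
        "p": r.p,
        "q": r.q,
        "associated_group": r.associated_group,
    }


def analyze_cohort(
    cohort: Cohort,
    cbs_n_perm: int = 128,
    cbs_alpha: float = 0.01,
    seed: int = 0,
    q_cut: float = 0.05,
    p_cut: float = 0.05,
    min_altered: int = 2,
    floor: float = 100.0,
) -> dict:
    """Run the discovery chain in memory: segment -> call -> differential
    screen (gains and losses) -> three-criterion candidate filter.

    Returns a dict with the smoothed matrix, call matrix, differential
    results and candidate list. This is the programmatic core of
    ``run_pipeline`` without file output or the optional stages.
    """
    from .expression import floor_filter

    smoothed, seg_map = segmentation.segment_cohort(
        cohort.probes, cohort.genome, alpha=cbs_alpha, n_perm=cbs_n_perm, seed=seed
    )
    params = calling.CnaCallParams()
    states = pd.DataFrame(
        calling.call_cna(smoothed.to_numpy(), params),
        index=smoothed.index,
        columns=smoothed.columns,
    )
    group_mask = cohort.group_mask
    differential = []
    for level in ("gain", "loss"):
        differential += stats.differential_cna(
            states, cohort.gene_map, group_mask, level=level,
            q_cut=q_cut, min_altered=min_altered,
        )
    expr = floor_filter(cohort.expression, floor=floor)
    candidates = integration.candidate_filter(
        differential, states, cohort.gene_map, expr, cohort.normal_pool,
        group_mask, p_cut=p_cut, q_cut=q_cut, min_altered=min_altered,
    )
    return {
        "smoothed": smoothed,
        "segments": seg_map,
        "states": states,
        "differential": differential,
        "candidates": candidates,
        "expression": expr,
    }


def demo_fixture_config(seed: int = 0) -> CohortConfig:
    """A small deterministic cohort: 20 + 30 samples, 2,000 probes over 10
    chromosomes, 300 genes, and 5 strongly planted dosage-coupled gains in
    two regions. Used by tests and documentation examples."""
    planted = (
        PlantedAlteration(
            name="gain_chr2",
            start_probe=250,
            end_probe=262,
            direction="gain",
            amplitude=1.5,
            freq_a=0.6,
            freq_b=0.02,
            genes={
                "G0000": (250, 256),
                "G0001": (253, 259),
                "G0002": (256, 262),
            },
        ),
        PlantedAlteration(
            name="gain_chr5",
            start_probe=850,
            end_probe=860,
            direction="gain",
            amplitude=1.5,
            freq_a=0.6,
            freq_b=0.02,
            genes={"G0003": (850, 856), "G0004": (854, 860)},
        ),
    )
    return CohortConfig(
        n_group_a=20,
        n_group_b=30,
        n_chrom=10,
        probes_per_chrom=200,
        n_genes=300,
        probe_noise_sd=0.1,
        segment_rate=0.3,
        planted=planted,
        dosage_slope=1.2,
        expression_noise_sd=0.3,
        seed=seed,
    )


def demo_fixture(seed: int = 0) -> Cohort:
    """Generate the packaged demo cohort (bit-identical for a given seed)."""
    return generate_cohort(demo_fixture_config(seed=seed))
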