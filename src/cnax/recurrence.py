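"""GISTIC-like recurrence scoring of copy-number alterations.

Each probe receives, per direction, a score f x a-bar: the fraction of
samples altered in that direction times the mean |smoothed log2| among the
altered samples. Significance comes from a permutation null that keeps each
sample's alteration burden but destroys locus recurrence: per iteration,
every sample's (state, amplitude) pairs are shuffled across probe positions
independently, and the null scores of all probes are pooled. Contiguous
significant probes merge into recurrent regions; gene-level recurrence uses
the max over a gene's probes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GScore", "RecurrentRegion", "gistic_scores", "significant_regions", "recurrent_genes"]

_LEVELS = {"gain": 1, "amp": 2, "loss": -1, "del": -2}


@dataclass
class GScore:
    probe: object
    direction: str
    frequency: float
    mean_amplitude: float
    score: float
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass
class RecurrentRegion:
    chrom: object
    start: int
    end: int
    direction: str
    peak_score: float
    n_probes: int
    genes: list
    frequency: float


def _direction_mask(states: np.ndarray, direction: str) -> np.ndarray:
    if direction == "gain":
        return states >= 1
    if direction == "loss":
        return states <= -1
    raise ValueError("direction must be 'gain' or 'loss'")


def _probe_scores(alt: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """f x a-bar per probe; zero where no sample is altered."""
    count = alt.sum(axis=0)
    f = count / alt.shape[0]
    total_amp = (amp * alt).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(count > 0, total_amp / np.maximum(count, 1), 0.0)
    return f * abar


def gistic_scores(
    smoothed: pd.DataFrame,
    states: pd.DataFrame,
    direction: str,
    n_boot: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[GScore]:
    """Score every probe and attach a permutation p-value.

    ``smoothed``/``states``: samples x probes frames on identical axes.
    Sampled null: p = (1 + #null >= observed) / (1 + n_null) pooled over all
    probes and iterations. ``exhaustive`` enumerates all per-sample probe
    permutations instead (tiny instances only) and drops the add-one
    correction, giving the exact pooled null fraction.
    """
    if n_boot < 100 and not exhaustive:
        warnings.warn(f"n_boot={n_boot} < 100: permutation p-values will be unstable")
    S = np.abs(smoothed.to_numpy(dtype=float))
    A = _direction_mask(states.to_numpy(), direction)
    n_samples, n_probes = A.shape
    obs = _probe_scores(A, S)

    if exhaustive:
        perms = list(itertools.permutations(range(n_probes)))
        null_scores = []
        for combo in itertools.product(perms, repeat=n_samples):
            idx = np.array(combo)
            a = np.take_along_axis(A, idx, axis=1)
            s = np.take_along_axis(S, idx, axis=1)
            null_scores.append(_probe_scores(a, s))
        null = np.concatenate(null_scores)
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        base = np.tile(np.arange(n_probes), (n_samples, 1))
        chunks = []
        for _ in range(n_boot):
            idx = rng.permuted(base, axis=1)
            a = np.take_along_axis(A, idx, axis=1)
            s = np.take_along_axis(S, idx, axis=1)
            chunks.append(_probe_scores(a, s))
        null = np.concatenate(chunks)
        add_one = 1

    null.sort()
    n_null = null.size
    # #null >= obs via right-tail position in the sorted pooled null
    geq = n_null - np.searchsorted(null, obs, side="left")
    pvals = (add_one + geq) / (add_one + n_null)

    probes = list(states.columns)
    counts = A.sum(axis=0)
    freqs = counts / n_samples
    abar = np.where(counts > 0, (S * A).sum(axis=0) / np.maximum(counts, 1), 0.0)
    return [
        GScore(
            probe=probes[i],
            direction=direction,
            frequency=float(freqs[i]),
            mean_amplitude=float(abar[i]),
            score=float(obs[i]),
            p_value=float(pvals[i]),
        )
        for i in range(n_probes)
    ]


def significant_regions(
    gscores: list[GScore],
    probes: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[RecurrentRegion]:
    """Merge maximal runs of contiguous significant probes into regions.

    ``probes`` carries chrom/start/end in genome order, aligned with the
    gscore list. ``gene_map`` (gene, start_probe, end_probe as global probe
    indices, half-open) annotates member genes.
    """
    chrom = probes["chrom"].to_numpy()
    start = probes["start"].to_numpy()
    end = probes["end"].to_numpy()
    sig = np.array([g.p_value < alpha for g in gscores])
    regions: list[RecurrentRegion] = []
    i = 0
    n = len(gscores)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and chrom[j + 1] == chrom[i]:
            j += 1
        members = range(i, j + 1)
        genes: list = []
        if gene_map is not None:
            hit = (gene_map["start_probe"] <= j) & (gene_map["end_probe"] > i)
            genes = list(gene_map.loc[hit, "gene"])
        regions.append(
            RecurrentRegion(
                chrom=chrom[i],
                start=int(start[i]),
                end=int(end[j]),
                direction=gscores[i].direction,
                peak_score=max(gscores[k].score for k in members),
                n_probes=j - i + 1,
                genes=genes,
                frequency=max(gscores[k].frequency for k in members),
            )
        )
        i = j + 1
    return regions


def recurrent_genes(
    states: pd.DataFrame,
    gene_map: pd.DataFrame,
    level: str,
    min_freq: float,
    group_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genes altered at ``level`` in at least ``min_freq`` of group samples.

    ``level`` in {gain, amp, loss, del}; a gene's frequency is the max over
    its probes of the per-probe alteration frequency. Returns a frame
    (gene, frequency) sorted by descending frequency then gene.
    """
    thr = _LEVELS[level]
    arr = states.to_numpy()
    if group_mask is not None:
        arr = arr[np.asarray(group_mask, dtype=bool)]
    n = arr.shape[0]
    if n == 0:
        raise ValueError("empty group")
    alt = arr >= thr if thr > 0 else arr <= thr
    probe_freq = alt.sum(axis=0) / n
    rows = []
    for _, g in gene_map.iterrows():
        f = float(probe_freq[int(g["start_probe"]) : int(g["end_probe"])].max(initial=0.0))
        if f >= min_freq and f > 0:
            rows.append({"gene": g["gene"], "frequency": f})
    out = pd.DataFrame(rows, columns=["gene", "frequency"])
    return out.sort_values(["frequency", "gene"], ascending=[False, True]).reset_index(drop=True)
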