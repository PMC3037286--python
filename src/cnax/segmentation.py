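"""Circular binary segmentation (CBS) of aCGH log2-ratio tracks.

Each chromosome is segmented independently. The current segment is treated
as a circle; the arc whose mean differs most from its complement -- the
arc maximizing the between-segment sum of squares, i.e. the two-sample t
with a constant variance scale -- is the candidate change, and the split is
accepted when its within-segment permutation p-value falls below ``alpha``
and every resulting piece keeps at least ``min_width`` probes.
Accepted splits are recursed until no further split is significant. Each
probe is then assigned the mean log2 ratio of its containing segment -- its
"smoothed" value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numba

import numpy as np
import pandas as pd

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 10_000
MIN_WIDTH = 5

__all__ = [
    "ProbeTrack",
    "Segment",
    "cbs_segment",
    "smooth_values",
    "segment_cohort",
    "segments_to_frame",
]


@dataclass
class ProbeTrack:
    """One sample's ordered aCGH probes.

    ``chrom``/``start``/``end`` describe probe positions (bp, half-open);
    ``log2`` holds the per-probe log2 ratios. Probes must be sorted by
    (chrom, start); chromosome blocks are contiguous.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    log2: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.log2 = np.asarray(self.log2, dtype=float)
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.log2)):
            raise ValueError("probe track arrays must have equal length")
        for c in pd.unique(self.chrom):
            pos = self.start[self.chrom == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"probes on chromosome {c!r} are not position-sorted")

    @classmethod
    def from_frame(cls, probes: pd.DataFrame, values: np.ndarray) -> "ProbeTrack":
        return cls(
            chrom=probes["chrom"].to_numpy(),
            start=probes["start"].to_numpy(),
            end=probes["end"].to_numpy(),
            log2=np.asarray(values, dtype=float),
        )

    def __len__(self) -> int:
        return len(self.log2)


@dataclass
class Segment:
    """A constant-copy-number run of consecutive probes on one chromosome.

    Probe indices are 0-based within the chromosome and inclusive;
    positions are bp. ``mean_log2`` is the arithmetic mean of member
    probes' log2 ratios (the smoothed value assigned back to each probe).
    """

    chrom: object
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int
    n_probes: int
    mean_log2: float
    note: str = field(default="")


@lru_cache(maxsize=512)
def _arc_index(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All admissible arcs [i, j) in a segment of ``n`` probes, flattened.

    An arc splits the linear segment into up to three pieces; it is
    admissible when arc and complement both have >= min_width probes and
    every nonempty linear piece keeps >= min_width probes, so no emitted
    segment can fall below the width floor. Ordered by (length, start).
    """
    starts_all, ends_all = [], []
    for length in range(min_width, n - min_width + 1):
        i = np.arange(0, n - length + 1)
        left_ok = (i == 0) | (i >= min_width)
        right = n - i - length
        right_ok = (right == 0) | (right >= min_width)
        i = i[left_ok & right_ok]
        starts_all.append(i)
        ends_all.append(i + length)
    if not starts_all:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return (
        np.concatenate(starts_all).astype(np.int64),
        np.concatenate(ends_all).astype(np.int64),
    )


@numba.njit(cache=False, fastmath=False)
def _split_stat_scan(S, starts, ends, n):  # pragma: no cover - jit
    """Per-row max of the split statistic over all candidate arcs.

    The statistic is the between-segment sum of squares of the circular
    split, n1*n2/n * (mean_arc - mean_complement)^2 -- the squared
    two-sample t with the segment-wide variance as the (constant) scale,
    so its argmax is exactly the split minimizing within-segment SSE.
    ``S``: (B, n+1) prefix sums per row.
    """
    B = S.shape[0]
    k = starts.shape[0]
    out = np.empty(B)
    for b in range(B):
        total = S[b, n]
        best = -np.inf
        for c in range(k):
            i = starts[c]
            j = ends[c]
            n1 = j - i
            n2 = n - n1
            sa = S[b, j] - S[b, i]
            d = sa / n1 - (total - sa) / n2
            t2 = d * d * n1 * n2 / n
            if t2 > best:
                best = t2
        out[b] = best
    return out


@numba.njit(cache=False, fastmath=False)
def _best_arc_kernel(S, starts, ends, n):  # pragma: no cover - jit
    """(max statistic, start, end) for one row; ties -> smaller start,
    then shorter arc (candidates arrive sorted by length then start, so
    the tie rule needs an explicit comparison)."""
    k = starts.shape[0]
    best = -np.inf
    bi = -1
    bj = -1
    total = S[0, n]
    for c in range(k):
        i = starts[c]
        j = ends[c]
        n1 = j - i
        n2 = n - n1
        sa = S[0, j] - S[0, i]
        d = sa / n1 - (total - sa) / n2
        t2 = d * d * n1 * n2 / n
        if t2 > best or (t2 == best and (i < bi or (i == bi and j - i < bj - bi))):
            best = t2
            bi = i
            bj = j
    return best, bi, bj


def _prefix(X: np.ndarray) -> np.ndarray:
    z = np.zeros((X.shape[0], 1))
    return np.concatenate((z, np.cumsum(X, axis=1)), axis=1)


def _best_arc(x: np.ndarray, min_width: int):
    """Arc maximizing the split statistic vs complement; ties -> smaller
    start, then shorter arc. Returns (stat, i, j), or (nan, -1, -1) when no
    admissible arc exists."""
    n = len(x)
    starts, ends = _arc_index(n, min_width)
    if starts.size == 0:
        return np.nan, -1, -1
    S = _prefix(x[None, :])
    t2, i, j = _best_arc_kernel(S, starts, ends, n)
    return float(t2), int(i), int(j)


def _perm_max_t(x: np.ndarray, min_width: int, rng: np.random.Generator, n_rows: int) -> np.ndarray:
    """Max split statistic over admissible arcs for ``n_rows`` permutations."""
    starts, ends = _arc_index(len(x), min_width)
    X = rng.permuted(np.tile(x, (n_rows, 1)), axis=1)
    S = _prefix(X)
    return _split_stat_scan(S, starts, ends, len(x))


def _split_significant(
    x: np.ndarray,
    tmax: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    batch: int = 64,
) -> bool:
    """Permutation test of the best split: p = (1+exceed)/(1+n_perm) < alpha.

    Permutations are abandoned early once enough of them reach ``tmax`` to
    make p >= alpha certain; this cannot change the accept/reject decision.
    """
    if not np.isfinite(tmax) and tmax != np.inf:
        return False
    reject_at = alpha * (n_perm + 1) - 1  # exceedances beyond this force p >= alpha
    exceed = 0
    done = 0
    first = True
    while done < n_perm:
        # a small first batch rejects the overwhelmingly common null case
        # after a handful of permutations
        b = min(16 if first else batch, n_perm - done)
        first = False
        tm = _perm_max_t(x, min_width, rng, b)
        exceed += int(np.count_nonzero(tm >= tmax))
        done += b
        if exceed > reject_at:
            return False
    return (1 + exceed) / (1 + n_perm) < alpha


def _segment_chromosome(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_width: int,
    seed: int,
    chrom_key: int,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns probe-index intervals [s, e)."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        s, e = stack.pop()
        seg = x[s:e]
        if e - s < 2 * min_width:
            out.append((s, e))
            continue
        tmax, i, j = _best_arc(seg, min_width)
        if i < 0 or tmax <= 0:
            out.append((s, e))
            continue
        # Permutation stream depends only on (seed, chromosome, bounds) so
        # decisions are reproducible and monotone in alpha.
        rng = np.random.default_rng([seed & 0x7FFFFFFF, chrom_key, s, e])
        if _split_significant(seg, tmax, alpha, n_perm, min_width, rng):
            for a, b in ((s, s + i), (s + i, s + j), (s + j, e)):
                if b > a:
                    stack.append((a, b))
        else:
            out.append((s, e))
    out.sort()
    return out


def cbs_segment(
    track: ProbeTrack,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_width: int = MIN_WIDTH,
    seed: int = 0,
) -> list[Segment]:
    """Segment one sample's track into constant-copy-number segments.

    Chromosomes are processed independently, in order of appearance. A
    chromosome with fewer than ``min_width`` probes cannot carry a valid
    segment and is returned whole, flagged "too short to split".
    """
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    segments: list[Segment] = []
    chroms = pd.unique(track.chrom)
    for ci, c in enumerate(chroms):
        mask = track.chrom == c
        idx = np.flatnonzero(mask)
        x = track.log2[idx]
        if len(x) < min_width:
            warnings.warn(f"chromosome {c!r} has {len(x)} probes (< {min_width}): too short to split")
            intervals = [(0, len(x))]
            note = "too short to split"
        else:
            intervals = _segment_chromosome(x, alpha, n_perm, min_width, seed, ci)
            note = ""
        for s, e in intervals:
            segments.append(
                Segment(
                    chrom=c,
                    start_index=s,
                    end_index=e - 1,
                    start_pos=int(track.start[idx[s]]),
                    end_pos=int(track.end[idx[e - 1]]),
                    n_probes=e - s,
                    mean_log2=float(np.mean(x[s:e])),
                    note=note,
                )
            )
    return segments


def smooth_values(track: ProbeTrack, segments: list[Segment]) -> np.ndarray:
    """Per-probe smoothed vector: probe i gets its segment's mean log2."""
    smoothed = np.full(len(track), np.nan)
    chrom_offsets = {}
    chroms = pd.unique(track.chrom)
    for c in chroms:
        chrom_offsets[c] = int(np.flatnonzero(track.chrom == c)[0])
    for seg in segments:
        off = chrom_offsets[seg.chrom]
        smoothed[off + seg.start_index : off + seg.end_index + 1] = seg.mean_log2
    if np.any(np.isnan(smoothed)):
        raise RuntimeError("segments do not cover every probe of the track")
    return smoothed


def segment_cohort(
    probes: pd.DataFrame,
    genome: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_width: int = MIN_WIDTH,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[Segment]]]:
    """Segment every sample of a cohort.

    ``probes``: frame with chrom/start/end rows in genome order.
    ``genome``: samples x probes log2-ratio frame (columns align with probes).
    Returns (smoothed samples x probes frame, per-sample segment lists).
    """
    smoothed = np.empty(genome.shape)
    seg_map: dict[str, list[Segment]] = {}
    for r, (sample, row) in enumerate(genome.iterrows()):
        track = ProbeTrack.from_frame(probes, row.to_numpy())
        segs = cbs_segment(track, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)
        seg_map[sample] = segs
        smoothed[r] = smooth_values(track, segs)
    return pd.DataFrame(smoothed, index=genome.index, columns=genome.columns), seg_map


def segments_to_bed(segments: list[Segment], name_prefix: str = "seg") -> str:
    """BED text (chrom, start, end, name, score) for one sample's segments.

    Coordinates are 0-based half-open per BED convention; column 5 carries
    the raw segment mean log2 (modern BED consumers tolerate floats)."""
    lines = [
        f"{s.chrom}\t{s.start_pos}\t{s.end_pos}\t{name_prefix}{i}\t{s.mean_log2:.4f}"
        for i, s in enumerate(segments)
    ]
    return "\n".join(lines) + "\n"


def segments_to_frame(seg_map: dict[str, list[Segment]]) -> pd.DataFrame:
    """SEG-like table (sample, chrom, start, end, n_probes, mean_log2)."""
    rows = [
        {
            "sample": sample,
            "chrom": seg.chrom,
            "start": seg.start_pos,
            "end": seg.end_pos,
            "n_probes": seg.n_probes,
            "mean_log2": seg.mean_log2,
        }
        for sample, segs in seg_map.items()
        for seg in segs
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_probes", "mean_log2"])
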