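"""Discrete CNA calls from smoothed log2 ratios, per-sample burden,
genomic-pattern classification, and per-group alteration frequencies.

Two thresholds on |smoothed log2 ratio| separate low-level from high-level
changes: 0.5 (gain/loss) and 1.0 (amplification/deletion), both strict.
States are coded -2 (deletion), -1 (loss), 0 (neutral), +1 (gain),
+2 (amplification), with homozygous deletion reported as -2 under a modal
diploid assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "CnaCallParams",
    "PatternParams",
    "PatternClass",
    "call_cna",
    "altered_fraction",
    "classify_pattern",
    "group_frequencies",
]


@dataclass(frozen=True)
class CnaCallParams:
    low_threshold: float = 0.5
    high_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.low_threshold < self.high_threshold:
            raise ValueError("thresholds must satisfy 0 < low < high")


class PatternClass(str, Enum):
    SIMPLEX = "simplex"
    SAWTOOTH = "complex_sawtooth"
    FIRESTORM = "complex_firestorm"


@dataclass(frozen=True)
class PatternParams:
    """Decision rule for genome-profile classes.

    firestorm: >=2 high-level segments within ``firestorm_window_bp`` on one
    chromosome (a clustered amplicon); else sawtooth when the profile carries
    >= ``sawtooth_min_segments`` altered segments or >=
    ``sawtooth_min_fraction`` percent altered probes; else simplex.
    """

    firestorm_window_bp: int = 20_000_000
    sawtooth_min_segments: int = 40
    sawtooth_min_fraction: float = 20.0


def call_cna(smoothed: np.ndarray, params: CnaCallParams = CnaCallParams()) -> np.ndarray:
    """Threshold smoothed values into {-2,-1,0,+1,+2} (strict > at each cut)."""
    smoothed = np.asarray(smoothed, dtype=float)
    if not np.all(np.isfinite(smoothed)):
        raise ValueError("smoothed values must be finite")
    states = np.zeros(smoothed.shape, dtype=np.int8)
    a = np.abs(smoothed)
    sign = np.sign(smoothed).astype(np.int8)
    states[a > params.low_threshold] = 1
    states[a > params.high_threshold] = 2
    return states * sign


def altered_fraction(states: np.ndarray) -> float:
    """Percentage of probes with a nonzero CNA state."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state vector")
    return 100.0 * np.count_nonzero(states) / states.size


def classify_pattern(
    segments: list[Segment],
    states: np.ndarray,
    call_params: CnaCallParams = CnaCallParams(),
    pattern_params: PatternParams = PatternParams(),
) -> PatternClass:
    """Classify one sample's genome profile.

    ``segments``/``states`` are the sample's segmentation and per-probe CNA
    calls. The rule is invariant to chromosome relabeling: clustering of
    high-level segments is judged within each chromosome by position only.
    """
    high: dict[object, list[tuple[int, int]]] = {}
    n_altered_segments = 0
    for seg in segments:
        a = abs(seg.mean_log2)
        if a > call_params.low_threshold:
            n_altered_segments += 1
        if a > call_params.high_threshold:
            high.setdefault(seg.chrom, []).append((seg.start_pos, seg.end_pos))
    for spans in high.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 - e1 <= pattern_params.firestorm_window_bp:
                return PatternClass.FIRESTORM
    frac = altered_fraction(states)
    if n_altered_segments >= pattern_params.sawtooth_min_segments or frac >= pattern_params.sawtooth_min_fraction:
        return PatternClass.SAWTOOTH
    return PatternClass.SIMPLEX


def group_frequencies(states: pd.DataFrame, group_mask: np.ndarray) -> pd.DataFrame:
    """Per-probe gain/loss frequencies within one sample group.

    ``states``: samples x probes call matrix. Returns a frame indexed by
    probe with columns freq_gain / freq_loss / freq_neutral summing to 1.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() == 0:
        raise ValueError("empty group")
    sub = states.to_numpy()[group_mask]
    n = sub.shape[0]
    gain = (sub >= 1).sum(axis=0) / n
    loss = (sub <= -1).sum(axis=0) / n
    return pd.DataFrame(
        {"freq_gain": gain, "freq_loss": loss, "freq_neutral": 1.0 - gain - loss},
        index=states.columns,
    )
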