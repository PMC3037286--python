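"""Group-comparison statistics: exact association tests, FDR control, and
the per-gene differential-CNA screen.

Fisher's exact test uses the two-sided probability-mass convention (sum the
probabilities of all tables with fixed margins whose point probability does
not exceed the observed table's), extended to r x c tables by full
enumeration (Freeman-Halton). Multiple testing is controlled with the
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "bh_fdr",
    "differential_cna",
    "annotation_association",
    "gene_alteration_matrix",
    "DifferentialCnaResult",
]

_LEVELS = {"gain": 1, "amp": 2, "loss": -1, "del": -2}
_REL_EPS = 1e-7  # tolerance when comparing table probabilities (R convention)


@dataclass
class DifferentialCnaResult:
    gene: str
    direction: str
    altered_a: int
    n_a: int
    altered_b: int
    n_b: int
    p: float
    q: float
    associated_group: str


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    lp = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    lp -= lgamma(n + 1)
    lp -= sum(lgamma(v + 1) for v in table.ravel())
    return lp


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, remaining_cols):
        if i == r - 1:
            last = remaining_cols
            if np.all(last >= 0) and last.sum() == row_sums[-1]:
                table[-1] = last
                yield table
            return
        def fill_row(j: int, left: int):
            if j == c - 1:
                if 0 <= left <= remaining_cols[-1]:
                    table[i, j] = left
                    yield True
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v)
        for _ in fill_row(0, row_sums[i]):
            yield from fill(i + 1, remaining_cols - table[i])

    yield from fill(0, np.array(col_sums, dtype=np.int64))


def fisher_exact(table) -> float:
    """Two-sided exact p for an r x c contingency table of counts.

    2 x 2 tables use the hypergeometric test directly; larger tables use the
    Freeman-Halton extension by enumerating every table with the observed
    margins (suitable for the small tables of annotation screens). A table
    with an empty row or column margin carries no information: p = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        warnings.warn("table has an empty margin; p = 1")
        return 1.0
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    n = int(t.sum())
    lp_obs = _log_table_prob(t, row_sums, col_sums, n)
    cutoff = lp_obs + _REL_EPS
    total = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(cand, row_sums, col_sums, n)
        if lp <= cutoff:
            total += np.exp(lp)
    return float(min(total, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=i} (m/j) p_(j)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_alteration_matrix(
    states: pd.DataFrame, gene_map: pd.DataFrame, level: str
) -> pd.DataFrame:
    """samples x genes boolean frame: any probe of the gene meets ``level``.

    ``level`` in {gain, amp, loss, del}; gene probe intervals are global
    half-open [start_probe, end_probe).
    """
    thr = _LEVELS[level]
    arr = states.to_numpy()
    alt = arr >= thr if thr > 0 else arr <= thr
    cum = np.concatenate(
        [np.zeros((alt.shape[0], 1), dtype=np.int64), np.cumsum(alt, axis=1)], axis=1
    )
    s = gene_map["start_probe"].to_numpy(dtype=np.int64)
    e = gene_map["end_probe"].to_numpy(dtype=np.int64)
    out = (cum[:, e] - cum[:, s]) > 0
    return pd.DataFrame(out, index=states.index, columns=list(gene_map["gene"]))


def differential_cna(
    states: pd.DataFrame,
    gene_map: pd.DataFrame,
    group_mask: np.ndarray,
    level: str = "gain",
    q_cut: float = 0.05,
    min_altered: int = 2,
) -> list[DifferentialCnaResult]:
    """Per-gene screen for CNA frequencies that differ between two groups.

    For every gene altered at ``level`` in at least ``min_altered`` samples,
    a 2 x 2 Fisher test compares altered/not-altered counts between group A
    (``group_mask``) and group B, with BH correction across the tested
    genes. Genes at q < ``q_cut`` are returned, each labeled with the group
    showing the higher alteration frequency.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    n_a = int(group_mask.sum())
    n_b = int((~group_mask).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    alt = gene_alteration_matrix(states, gene_map, level)
    counts = alt.sum(axis=0)
    tested = [g for g in alt.columns if counts[g] >= min_altered]
    pvals = []
    tables = []
    for g in tested:
        col = alt[g].to_numpy()
        ka = int(col[group_mask].sum())
        kb = int(col[~group_mask].sum())
        tables.append((ka, kb))
        pvals.append(fisher_exact([[ka, n_a - ka], [kb, n_b - kb]]))
    if not tested:
        return []
    qvals = bh_fdr(pvals)
    out = []
    for g, (ka, kb), p, q in zip(tested, tables, pvals, qvals):
        if q < q_cut:
            assoc = "A" if ka / n_a >= kb / n_b else "B"
            out.append(
                DifferentialCnaResult(
                    gene=g,
                    direction=level,
                    altered_a=ka,
                    n_a=n_a,
                    altered_b=kb,
                    n_b=n_b,
                    p=float(p),
                    q=float(q),
                    associated_group=assoc,
                )
            )
    return out


def annotation_association(
    annotations: pd.DataFrame,
    group_mask: np.ndarray,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature association with the two-group split.

    Categorical features: Fisher exact on the groups x categories table
    (missing values dropped per feature). Continuous features: two-sided
    Mann-Whitney rank-sum. A feature constant across both groups is
    uninformative: p = 1.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    rows = []
    for col in categorical or []:
        vals = annotations[col]
        ok = vals.notna().to_numpy()
        sub, g = vals[ok], group_mask[ok]
        cats = sorted(sub.unique(), key=str)
        if len(cats) < 2:
            p = 1.0
        else:
            tab = np.array(
                [[int(((sub == c) & m).sum()) for c in cats] for m in (g, ~g)]
            )
            p = fisher_exact(tab)
        rows.append({"feature": col, "test": "fisher", "n": int(ok.sum()), "p": p})
    for col in continuous or []:
        vals = annotations[col]
        ok = vals.notna().to_numpy()
        a = vals[ok & group_mask].to_numpy(dtype=float)
        b = vals[ok & ~group_mask].to_numpy(dtype=float)
        if len(np.unique(np.concatenate([a, b]))) < 2:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": col, "test": "mann-whitney", "n": int(ok.sum()), "p": p})
    return pd.DataFrame(rows, columns=["feature", "test", "n", "p"])
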