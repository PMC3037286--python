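"""CNA-expression integration: probe-set matching, dosage-association
testing, and the three-criterion candidate-gene filter.

A gene enters the candidate screen only if its CNA frequency already
differs between the two groups (the differential screen). It becomes a
candidate when, in addition, (i) the frequency of the combined event
(gain with overexpression, or loss with underexpression) differs between
groups by Fisher's exact test, (ii) its expression tracks its copy-number
state (Student t-test, BH-corrected across tested genes, sign-concordant),
and (iii) its expression differs between groups (Student t-test,
sign-concordant). Over/underexpression calls compare each sample to the
normal-pool reference at +-1 log2 (twice / half the pool level).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import DifferentialCnaResult, bh_fdr, fisher_exact, gene_alteration_matrix

__all__ = [
    "ProbeMatch",
    "CandidateGene",
    "match_probes",
    "expression_calls",
    "cna_expression_association",
    "correlated_fraction",
    "candidate_filter",
]

_TIER1 = re.compile(r"^[^_]+_at$")       # plain "_at", no suffix letter
_TIER2 = re.compile(r"^.+_s_at$")


@dataclass
class ProbeMatch:
    gene: str
    probeset: str
    tier: int
    median: float


@dataclass
class CandidateGene:
    gene: str
    direction: str                  # "gain" or "loss"
    combined_a: int
    n_a: int
    combined_b: int
    n_b: int
    p_combined: float               # criterion (i)
    q_dosage: float                 # criterion (ii)
    p_expression: float             # criterion (iii)
    passes: bool


def _tier(probeset: str) -> int:
    if _TIER1.match(probeset):
        return 1
    if _TIER2.match(probeset):
        return 2
    return 3


def match_probes(
    probeset_expression: pd.DataFrame, probeset_to_gene: pd.Series
) -> list[ProbeMatch]:
    """Pick one expression probe set per gene.

    ``probeset_expression``: probesets x samples (log2);
    ``probeset_to_gene``: probeset -> gene symbol. Probe sets with a bare
    "_at" extension are preferred, then "_s_at", then everything else;
    within the winning tier the probe set with the highest median
    expression is kept. Fully deterministic (median ties break by probe-set
    id order).
    """
    med = probeset_expression.median(axis=1)
    out: list[ProbeMatch] = []
    for gene, group in probeset_to_gene.groupby(probeset_to_gene):
        candidates = sorted(group.index)
        best_tier = min(_tier(ps) for ps in candidates)
        in_tier = [ps for ps in candidates if _tier(ps) == best_tier]
        # highest median within the tier; exact ties break by id order
        top = max(med[ps] for ps in in_tier)
        chosen = sorted(ps for ps in in_tier if med[ps] == top)[0]
        out.append(ProbeMatch(gene=str(gene), probeset=chosen, tier=best_tier, median=float(med[chosen])))
    return sorted(out, key=lambda m: m.gene)


def expression_calls(
    expression: pd.DataFrame, normal_pool: pd.Series, threshold: float = 1.0
) -> pd.DataFrame:
    """Ternary over/normal/under calls vs the normal-pool reference.

    ``expression``: genes x samples log2; ``normal_pool``: per-gene log2
    reference. over (+1) when sample - pool >= threshold; under (-1) when
    <= -threshold; else 0.
    """
    diff = expression.sub(normal_pool.loc[expression.index], axis=0)
    calls = np.zeros(diff.shape, dtype=np.int8)
    calls[diff.to_numpy() >= threshold] = 1
    calls[diff.to_numpy() <= -threshold] = -1
    return pd.DataFrame(calls, index=expression.index, columns=expression.columns)


def cna_expression_association(
    gene_alt: pd.DataFrame,
    expression: pd.DataFrame,
    direction: str,
    min_altered: int = 2,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Dosage test: does expression differ between altered and unaltered
    samples?

    ``gene_alt``: samples x genes boolean alteration matrix (one direction);
    ``expression``: genes x samples log2. Genes altered in fewer than
    ``min_altered`` samples, or altered in all samples, are skipped with a
    reason. A gene is ``correlated`` when its BH q < ``q_cut`` and the mean
    shift matches the direction (gain -> higher, loss -> lower).
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    genes = [g for g in gene_alt.columns if g in expression.index]
    rows = []
    for g in genes:
        mask = gene_alt[g].to_numpy(dtype=bool)
        n_alt = int(mask.sum())
        if n_alt < min_altered:
            rows.append({"gene": g, "n_altered": n_alt, "tested": False,
                         "reason": f"altered in {n_alt} < {min_altered} samples",
                         "t": np.nan, "p": np.nan})
            continue
        if n_alt == len(mask):
            rows.append({"gene": g, "n_altered": n_alt, "tested": False,
                         "reason": "altered in all samples", "t": np.nan, "p": np.nan})
            continue
        expr = expression.loc[g, gene_alt.index].to_numpy(dtype=float)
        t, p = sps.ttest_ind(expr[mask], expr[~mask], equal_var=True)
        if np.isnan(p):  # zero variance in both strata, identical means
            t, p = 0.0, 1.0
        rows.append({"gene": g, "n_altered": n_alt, "tested": True, "reason": "",
                     "t": float(t), "p": float(p)})
    res = pd.DataFrame(rows, columns=["gene", "n_altered", "tested", "reason", "t", "p"])
    res["q"] = np.nan
    tested = res["tested"].to_numpy()
    if tested.any():
        res.loc[tested, "q"] = bh_fdr(res.loc[tested, "p"].to_numpy())
    want_sign = 1.0 if direction == "gain" else -1.0
    res["correlated"] = tested & (res["q"] < q_cut) & (np.sign(res["t"]) == want_sign)
    return res


def correlated_fraction(results: pd.DataFrame) -> float:
    """Percentage of tested genes whose expression tracks the CNA."""
    tested = int(results["tested"].sum())
    if tested == 0:
        return 0.0
    return 100.0 * int(results["correlated"].sum()) / tested


def candidate_filter(
    differential: list[DifferentialCnaResult],
    states: pd.DataFrame,
    gene_map: pd.DataFrame,
    expression: pd.DataFrame,
    normal_pool: pd.Series,
    group_mask: np.ndarray,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
    min_altered: int = 2,
    call_threshold: float = 1.0,
) -> list[CandidateGene]:
    """Three-criterion candidate screen over the differential gene list.

    ``differential`` must come from the differential-CNA screen (gain- or
    loss-direction results; each gene is evaluated in its screened
    direction). ``states``: samples x probes calls; ``expression``: genes x
    samples log2. Output is sorted by gene position (gene_map order) then
    symbol; only passing genes are returned.
    """
    if not differential:
        warnings.warn("empty differential gene list; no candidates to screen")
        return []
    group_mask = np.asarray(group_mask, dtype=bool)
    n_a = int(group_mask.sum())
    n_b = int((~group_mask).sum())
    calls = expression_calls(expression, normal_pool, threshold=call_threshold)

    by_dir: dict[str, list[DifferentialCnaResult]] = {}
    for r in differential:
        d = "gain" if r.direction in ("gain", "amp") else "loss"
        by_dir.setdefault(d, []).append(r)

    order = {g: i for i, g in enumerate(gene_map["gene"])}
    out: list[CandidateGene] = []
    for d, results in by_dir.items():
        genes = [r.gene for r in results]
        gmap = gene_map[gene_map["gene"].isin(genes)]
        alt = gene_alteration_matrix(states, gmap, "gain" if d == "gain" else "loss")
        # criterion (ii): dosage association on the full cohort, BH across
        # the tested differential genes of this direction
        assoc = cna_expression_association(
            alt, expression, direction=d, min_altered=min_altered, q_cut=q_cut
        ).set_index("gene")
        want_call = 1 if d == "gain" else -1
        for r in results:
            g = r.gene
            if g not in alt.columns or g not in expression.index:
                continue
            a = alt[g].to_numpy(dtype=bool)
            c = calls.loc[g, alt.index].to_numpy() == want_call
            combined = a & c
            ka = int(combined[group_mask].sum())
            kb = int(combined[~group_mask].sum())
            p_comb = fisher_exact([[ka, n_a - ka], [kb, n_b - kb]])
            corr = bool(assoc.loc[g, "correlated"]) if g in assoc.index else False
            q_dos = float(assoc.loc[g, "q"]) if g in assoc.index else np.nan
            ea = expression.loc[g, alt.index].to_numpy(dtype=float)[group_mask]
            eb = expression.loc[g, alt.index].to_numpy(dtype=float)[~group_mask]
            t_expr, p_expr = sps.ttest_ind(ea, eb, equal_var=True)
            if np.isnan(p_expr):
                t_expr, p_expr = 0.0, 1.0
            sign_ok = np.sign(t_expr) == (1.0 if d == "gain" else -1.0)
            passes = (p_comb < p_cut) and corr and (p_expr < p_cut) and bool(sign_ok)
            if passes:
                out.append(
                    CandidateGene(
                        gene=g,
                        direction=d,
                        combined_a=ka,
                        n_a=n_a,
                        combined_b=kb,
                        n_b=n_b,
                        p_combined=float(p_comb),
                        q_dosage=q_dos,
                        p_expression=float(p_expr),
                        passes=True,
                    )
                )
    return sorted(out, key=lambda c: (order.get(c.gene, len(order)), c.gene))
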