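import numpy as np
import pandas as pd
import pytest

from cnax.integration import (
    candidate_filter,
    cna_expression_association,
    correlated_fraction,
    expression_calls,
    match_probes,
)
from cnax.stats import DifferentialCnaResult


class TestMatchProbes:
    def make(self, mapping, medians):
        samples = [f"s{j}" for j in range(3)]
        rows = {ps: [m, m, m] for ps, m in medians.items()}
        expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        return expr, pd.Series(mapping)

    def test_plain_at_beats_s_at(self):
        expr, p2g = self.make({"1007_s_at": "TP", "1007_at": "TP"},
                              {"1007_s_at": 9.0, "1007_at": 5.0})
        (m,) = match_probes(expr, p2g)
        assert m.probeset == "1007_at"
        assert m.tier == 1

    def test_s_at_beats_x_at(self):
        expr, p2g = self.make({"201_s_at": "G", "201_x_at": "G"},
                              {"201_s_at": 4.0, "201_x_at": 8.0})
        (m,) = match_probes(expr, p2g)
        assert m.probeset == "201_s_at"
        assert m.tier == 2

    def test_highest_median_within_tier(self):
        expr, p2g = self.make({"11_at": "G", "22_at": "G"},
                              {"11_at": 8.1, "22_at": 7.9})
        (m,) = match_probes(expr, p2g)
        assert m.probeset == "11_at"
        assert m.median == pytest.approx(8.1)

    def test_deterministic_on_median_ties(self):
        expr, p2g = self.make({"22_at": "G", "11_at": "G"}, {"22_at": 7.0, "11_at": 7.0})
        (m,) = match_probes(expr, p2g)
        assert m.probeset == "11_at"


class TestExpressionCalls:
    def test_threshold_boundaries(self):
        pool = pd.Series({"g": 6.0})
        expr = pd.DataFrame({"s0": [7.0], "s1": [6.99], "s2": [5.0], "s3": [5.01]},
                            index=["g"])
        calls = expression_calls(expr, pool)
        assert list(calls.loc["g"]) == [1, 0, -1, 0]


class TestCnaExpressionAssociation:
    def make_alt(self, mask):
        return pd.DataFrame({"g": mask}, index=[f"s{i}" for i in range(len(mask))])

    def test_identical_strata_not_correlated(self):
        alt = self.make_alt([True, True, False, False, False])
        expr = pd.DataFrame([[5.0] * 5], index=["g"], columns=alt.index)
        res = cna_expression_association(alt, expr, "gain")
        assert res.loc[0, "p"] == 1.0
        assert not res.loc[0, "correlated"]

    def test_planted_dosage_coupling_detected(self, rng):
        carriers = np.r_[np.ones(15, bool), np.zeros(35, bool)]
        alt = self.make_alt(carriers)
        vals = 7.0 + 1.0 * carriers + rng.normal(0, 0.2, 50)
        expr = pd.DataFrame([vals], index=["g"], columns=alt.index)
        res = cna_expression_association(alt, expr, "gain")
        assert res.loc[0, "correlated"]

    def test_loss_requires_downshift(self, rng):
        carriers = np.r_[np.ones(15, bool), np.zeros(35, bool)]
        alt = self.make_alt(carriers)
        vals = 7.0 + 1.0 * carriers + rng.normal(0, 0.2, 50)  # up, not down
        expr = pd.DataFrame([vals], index=["g"], columns=alt.index)
        res = cna_expression_association(alt, expr, "loss")
        assert not res.loc[0, "correlated"]

    def test_single_altered_sample_excluded(self, rng):
        alt = self.make_alt([True] + [False] * 9)
        expr = pd.DataFrame([rng.normal(7, 1, 10)], index=["g"], columns=alt.index)
        res = cna_expression_association(alt, expr, "gain")
        assert not res.loc[0, "tested"]
        assert "altered in 1" in res.loc[0, "reason"]

    def test_fully_altered_gene_skipped(self, rng):
        alt = self.make_alt([True] * 8)
        expr = pd.DataFrame([rng.normal(7, 1, 8)], index=["g"], columns=alt.index)
        res = cna_expression_association(alt, expr, "gain")
        assert not res.loc[0, "tested"]
        assert "all samples" in res.loc[0, "reason"]


def test_correlated_fraction_construction(rng):
    """A cohort built with 10% strongly dosage-coupled gained genes should
    report a correlated fraction close to 10%."""
    n_genes, n_samples = 50, 60
    coupled = set(range(5))
    carriers = rng.random((n_samples, n_genes)) < 0.4
    expr = np.tile(rng.normal(7, 0.5, n_genes), (n_samples, 1))
    for g in coupled:
        expr[:, g] += 2.0 * carriers[:, g]
    expr += rng.normal(0, 0.15, expr.shape)
    alt = pd.DataFrame(carriers, index=[f"s{i}" for i in range(n_samples)],
                       columns=[f"g{j}" for j in range(n_genes)])
    expr_df = pd.DataFrame(expr.T, index=alt.columns, columns=alt.index)
    res = cna_expression_association(alt, expr_df, "gain")
    assert correlated_fraction(res) == pytest.approx(10.0, abs=4.0)
    empty = res.copy()
    empty["correlated"] = False
    assert correlated_fraction(empty) == 0.0
    full = res.copy()
    full["correlated"] = full["tested"]
    assert correlated_fraction(full) == 100.0


def hand_cohort(rng, coupled=True, differential=True):
    """A small cohort with direct (no-segmentation) state matrices: one
    gene of interest plus background genes."""
    n_a, n_b = 30, 60
    n = n_a + n_b
    samples = [f"s{i}" for i in range(n)]
    mask = np.r_[np.ones(n_a, bool), np.zeros(n_b, bool)]
    freq_b = 0.5 if not differential else 0.03
    carriers = np.where(mask, rng.random(n) < 0.5, rng.random(n) < freq_b)
    states_arr = np.zeros((n, 12), dtype=int)
    states_arr[carriers, 2:8] = 1
    states = pd.DataFrame(states_arr, index=samples,
                          columns=[f"P{i}" for i in range(12)])
    gene_map = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"],
                             "start_probe": [2], "end_probe": [8]})
    pool = pd.Series({"G": 7.0})
    expr = 7.0 + (1.6 * carriers if coupled else 0.0) + rng.normal(0, 0.3, n)
    expression = pd.DataFrame([expr], index=["G"], columns=samples)
    diff = [
        DifferentialCnaResult(
            gene="G", direction="gain", altered_a=int(carriers[mask].sum()),
            n_a=n_a, altered_b=int(carriers[~mask].sum()), n_b=n_b,
            p=1e-6, q=1e-5, associated_group="A",
        )
    ]
    return diff, states, gene_map, expression, pool, mask


class TestCandidateFilter:
    def test_planted_candidate_passes_all_three(self, rng):
        diff, states, gm, expr, pool, mask = hand_cohort(rng)
        out = candidate_filter(diff, states, gm, expr, pool, mask)
        assert [c.gene for c in out] == ["G"]
        c = out[0]
        assert c.p_combined < 0.05 and c.p_expression < 0.05 and c.passes

    def test_equal_group_frequencies_fail_combined_criterion(self, rng):
        diff, states, gm, expr, pool, mask = hand_cohort(rng, differential=False)
        out = candidate_filter(diff, states, gm, expr, pool, mask)
        assert out == []

    def test_uncoupled_gene_fails_dosage_criterion(self, rng):
        diff, states, gm, expr, pool, mask = hand_cohort(rng, coupled=False)
        out = candidate_filter(diff, states, gm, expr, pool, mask)
        assert out == []

    def test_empty_differential_list_warns(self, rng):
        _, states, gm, expr, pool, mask = hand_cohort(rng)
        with pytest.warns(UserWarning, match="empty differential"):
            assert candidate_filter([], states, gm, expr, pool, mask) == []

    def test_tighter_cutoffs_never_grow_the_list(self, rng):
        diff, states, gm, expr, pool, mask = hand_cohort(rng)
        loose = candidate_filter(diff, states, gm, expr, pool, mask, p_cut=0.05)
        tight = candidate_filter(diff, states, gm, expr, pool, mask, p_cut=1e-12)
        assert {c.gene for c in tight} <= {c.gene for c in loose}


def test_candidates_contained_in_differential_list(demo_cohort, demo_analysis):
    differential_genes = {r.gene for r in demo_analysis["differential"]}
    for c in demo_analysis["candidates"]:
        assert c.gene in differential_genes


def test_demo_fixture_candidates_are_exactly_the_planted_genes(demo_cohort, demo_analysis):
    planted = {
        g for alt in demo_cohort.config.planted if alt.dosage_coupled for g in alt.genes
    }
    assert {c.gene for c in demo_analysis["candidates"]} == planted
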