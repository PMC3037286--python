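"""Exact-test and FDR machinery, checked against enumeration oracles and
published two-group contingency tables."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from cnax.stats import (
    annotation_association,
    bh_fdr,
    differential_cna,
    fisher_exact,
    gene_alteration_matrix,
)


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher by direct hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    # 2x2 and 3x2 tables from a published IBC vs nIBC clinical comparison;
    # expected p-values frozen after cross-checking with R's fisher.test.
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[33, 43], [30, 91]], 7.74e-3),            # ER status
            ([[30, 107], [19, 15]], 2.16e-4),           # ERBB2 status
            ([[15, 79], [28, 41]], 5.82e-4),            # P53 status
            ([[0, 32], [10, 62], [48, 38]], 1.35e-12),  # grade 1/2/3
            ([[16, 23], [27, 52], [6, 49]], 9.39e-4),   # genomic pattern
        ],
    )
    def test_published_contingency_tables(self, table, expected):
        p = fisher_exact(table)
        assert p == pytest.approx(expected, rel=5e-3)

    def test_balanced_table_gives_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_small_table_vs_enumeration(self):
        assert fisher_exact([[2, 1], [1, 2]]) == pytest.approx(
            fisher_2x2_oracle(2, 1, 1, 2)
        )

    def test_random_2x2_tables_match_enumeration(self, rng):
        for _ in range(40):
            a, b, c, d = rng.integers(0, 9, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_2x2_oracle(int(a), int(b), int(c), int(d))
            ), (a, b, c, d)

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 5, 2], [4, 1, 6]], 0.1214574899),
            ([[1, 3, 6], [2, 4, 0], [0, 5, 2]], 0.06165687859),
        ],
    )
    def test_freeman_halton_matches_reference(self, table, expected):
        # frozen reference values from R's fisher.test on the same tables
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-8)

    def test_empty_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="empty margin"):
            assert fisher_exact([[0, 0], [3, 5]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestBhFdr:
    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_matches_definition_on_random_vectors(self, rng):
        """q_i = min over j >= i (in sorted order) of (m/j) p_(j)."""
        for m in (5, 37, 400):
            p = rng.random(m)
            order = np.argsort(p)
            sorted_p = p[order]
            q_sorted = np.minimum.accumulate(
                (m / np.arange(m, 0, -1)) * sorted_p[::-1]
            )[::-1]
            q_oracle = np.empty(m)
            q_oracle[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(bh_fdr(p), q_oracle)

    def test_q_dominates_p(self, rng):
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()


def synthetic_states(rng, n_a=20, n_b=40, n_probes=60, freq_a=0.5, freq_b=0.05,
                     probes=range(10, 20)):
    """Call matrix with one planted differential gain region."""
    n = n_a + n_b
    arr = np.zeros((n, n_probes), dtype=int)
    carriers = np.r_[rng.random(n_a) < freq_a, rng.random(n_b) < freq_b]
    for s in np.flatnonzero(carriers):
        arr[s, list(probes)] = 1
    states = pd.DataFrame(arr, index=[f"S{i}" for i in range(n)],
                          columns=[f"P{i}" for i in range(n_probes)])
    mask = np.r_[np.ones(n_a, bool), np.zeros(n_b, bool)]
    return states, mask


GENE_MAP = pd.DataFrame(
    {
        "gene": ["G_in", "G_out"],
        "chrom": ["chr1", "chr1"],
        "start_probe": [12, 40],
        "end_probe": [18, 42],
    }
)


class TestDifferentialCna:
    def test_planted_difference_retained_with_group_label(self, rng):
        states, mask = synthetic_states(rng)
        res = differential_cna(states, GENE_MAP, mask, level="gain")
        genes = {r.gene: r for r in res}
        assert "G_in" in genes
        assert genes["G_in"].associated_group == "A"
        assert "G_out" not in genes

    def test_never_altered_gene_excluded_before_testing(self, rng):
        states, mask = synthetic_states(rng)
        res = differential_cna(states, GENE_MAP, mask, level="gain", q_cut=1.1)
        assert "G_out" not in {r.gene for r in res}

    def test_label_swap_symmetry(self, rng):
        states, mask = synthetic_states(rng)
        res_a = differential_cna(states, GENE_MAP, mask, level="gain")
        res_b = differential_cna(states, GENE_MAP, ~mask, level="gain")
        assert {r.gene for r in res_a} == {r.gene for r in res_b}
        for ra, rb in zip(res_a, res_b):
            assert ra.p == pytest.approx(rb.p)
            assert {ra.associated_group, rb.associated_group} == {"A", "B"}

    def test_equal_frequencies_rarely_retained(self):
        """Type-I control: a gene altered at the same rate in both groups
        should not survive the q < 0.05 screen in almost every replicate."""
        false_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            states, mask = synthetic_states(rng, freq_a=0.3, freq_b=0.3)
            res = differential_cna(states, GENE_MAP, mask, level="gain")
            false_hits += int("G_in" in {r.gene for r in res})
        assert false_hits <= 1

    def test_empty_group_rejected(self, rng):
        states, mask = synthetic_states(rng)
        with pytest.raises(ValueError):
            differential_cna(states, GENE_MAP, np.ones(len(mask), bool), level="gain")


def test_gene_alteration_matrix_any_probe_rule():
    arr = np.zeros((3, 10), dtype=int)
    arr[0, 5] = 2   # amp within G_a's interval
    arr[1, 9] = -1
    states = pd.DataFrame(arr, columns=[f"P{i}" for i in range(10)])
    gm = pd.DataFrame({"gene": ["G_a", "G_b"], "chrom": ["c", "c"],
                       "start_probe": [4, 8], "end_probe": [7, 10]})
    gains = gene_alteration_matrix(states, gm, "gain")
    losses = gene_alteration_matrix(states, gm, "loss")
    assert gains.loc[0, "G_a"] and not gains.loc[1, "G_a"]
    assert losses.loc[1, "G_b"] and not losses.loc[0, "G_b"]


class TestAnnotationAssociation:
    def test_group_linked_feature_detected_and_constant_feature_null(self, rng):
        n = 120
        mask = np.r_[np.ones(40, bool), np.zeros(80, bool)]
        linked = np.where(
            mask, rng.random(n) < 0.8, rng.random(n) < 0.2
        )
        ann = pd.DataFrame(
            {
                "linked": np.where(linked, "positive", "negative"),
                "flat": ["same"] * n,
                "age": rng.normal(55, 8, n) - 8 * mask,
            }
        )
        res = annotation_association(
            ann, mask, categorical=["linked", "flat"], continuous=["age"]
        ).set_index("feature")
        assert res.loc["linked", "p"] < 1e-6
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["age", "test"] == "mann-whitney"
        assert res.loc["age", "p"] < 0.05

    def test_missing_values_dropped_per_feature(self):
        ann = pd.DataFrame({"f": ["positive", None, "negative", "positive"]})
        res = annotation_association(ann, np.array([True, True, False, False]),
                                     categorical=["f"])
        assert res.loc[0, "n"] == 3
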