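import itertools

import numpy as np
import pandas as pd
import pytest

from cnax.recurrence import gistic_scores, recurrent_genes, significant_regions


def frames(states_arr, smoothed_arr=None):
    states = pd.DataFrame(np.asarray(states_arr))
    states.columns = [f"P{i}" for i in range(states.shape[1])]
    if smoothed_arr is None:
        smoothed_arr = np.asarray(states_arr, dtype=float)
    smoothed = pd.DataFrame(np.asarray(smoothed_arr, dtype=float),
                            columns=states.columns)
    return smoothed, states


def probe_meta(n, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": [chrom] * n, "start": np.arange(n) * 1000,
         "end": np.arange(n) * 1000 + 60}
    )


class TestGisticScores:
    def test_universal_gain_scores_one(self):
        arr = np.ones((10, 6))
        smoothed, states = frames(arr)
        gs = gistic_scores(smoothed, states, "gain", n_boot=100, seed=0)
        assert all(g.score == pytest.approx(1.0) for g in gs)

    def test_no_alterations_score_zero_p_one(self):
        smoothed, states = frames(np.zeros((5, 8), dtype=int))
        gs = gistic_scores(smoothed, states, "gain", n_boot=100, seed=0)
        assert all(g.score == 0.0 for g in gs)
        assert all(g.p_value == 1.0 for g in gs)

    def test_matches_exhaustive_permutation_oracle(self):
        """On a 3-sample x 4-probe instance, sampled-null p-values must be
        checked against a brute-force enumeration of every per-sample probe
        permutation (the add-one-free exact pooled null)."""
        states_arr = np.array(
            [[1, 1, 0, 0],
             [1, 0, 0, 1],
             [1, 1, 1, 0]]
        )
        smoothed_arr = np.array(
            [[0.8, 0.7, 0.0, 0.1],
             [0.9, 0.0, 0.2, 0.6],
             [1.2, 0.8, 0.7, 0.0]]
        )
        smoothed, states = frames(states_arr, smoothed_arr)

        def score(alt, amp):
            out = []
            for p in range(alt.shape[1]):
                altered = alt[:, p] == 1
                f = altered.mean()
                abar = amp[altered, p].mean() if altered.any() else 0.0
                out.append(f * abar)
            return out

        amp = np.abs(smoothed_arr)
        alt = (states_arr >= 1).astype(int)
        obs = score(alt, amp)
        null = []
        perms = list(itertools.permutations(range(4)))
        for combo in itertools.product(perms, repeat=3):
            a = np.vstack([alt[s, list(combo[s])] for s in range(3)])
            m = np.vstack([amp[s, list(combo[s])] for s in range(3)])
            null.extend(score(a, m))
        null = np.asarray(null)
        expected_p = [(null >= o).mean() for o in obs]

        gs = gistic_scores(smoothed, states, "gain", exhaustive=True)
        assert [g.score for g in gs] == pytest.approx(obs)
        assert [g.p_value for g in gs] == pytest.approx(expected_p)

    def test_sample_order_invariance(self, rng):
        arr = rng.integers(0, 2, size=(8, 12))
        sm = arr * rng.uniform(0.6, 1.4, size=arr.shape)
        smoothed, states = frames(arr, sm)
        gs1 = gistic_scores(smoothed, states, "gain", n_boot=200, seed=4)
        perm = rng.permutation(8)
        gs2 = gistic_scores(smoothed.iloc[perm], states.iloc[perm], "gain",
                            n_boot=200, seed=4)
        assert [g.score for g in gs1] == pytest.approx([g.score for g in gs2])

    def test_seed_reproducibility(self, rng):
        arr = rng.integers(0, 2, size=(6, 10))
        smoothed, states = frames(arr, arr * 0.8)
        p1 = [g.p_value for g in gistic_scores(smoothed, states, "gain", n_boot=300, seed=9)]
        p2 = [g.p_value for g in gistic_scores(smoothed, states, "gain", n_boot=300, seed=9)]
        assert p1 == p2

    def test_low_n_boot_warns(self):
        smoothed, states = frames(np.zeros((3, 4), dtype=int))
        with pytest.warns(UserWarning, match="unstable"):
            gistic_scores(smoothed, states, "gain", n_boot=50, seed=0)

    def test_nonrecurrent_null_rarely_significant(self, rng):
        """Random scattered alterations (no common locus) should leave at
        most roughly an alpha fraction of probes significant."""
        n_samples, n_probes = 30, 150
        arr = np.zeros((n_samples, n_probes), dtype=int)
        for s in range(n_samples):
            pos = rng.choice(n_probes, size=6, replace=False)
            arr[s, pos] = 1
        smoothed, states = frames(arr, arr * rng.uniform(0.6, 1.2, arr.shape))
        gs = gistic_scores(smoothed, states, "gain", n_boot=1000, seed=2)
        frac = np.mean([g.p_value < 0.05 for g in gs])
        assert frac <= 0.05 + 0.03


class TestSignificantRegions:
    def test_planted_region_recovered(self, rng):
        n_probes, n_samples = 400, 20
        arr = np.zeros((n_samples, n_probes), dtype=int)
        carriers = rng.random(n_samples) < 0.6
        arr[np.ix_(carriers, np.arange(100, 300))] = 1
        smoothed = arr * 0.8
        sm, st = frames(arr, smoothed)
        gs = gistic_scores(sm, st, "gain", n_boot=500, seed=1)
        regions = significant_regions(gs, probe_meta(n_probes))
        assert len(regions) == 1
        r = regions[0]
        sig_idx = [i for i, g in enumerate(gs) if g.p_value < 0.05]
        assert abs(min(sig_idx) - 100) <= 1
        assert abs(max(sig_idx) - 299) <= 1
        assert r.n_probes == len(sig_idx)

    def test_alpha_zero_gives_no_regions(self, rng):
        arr = rng.integers(0, 2, (6, 30))
        sm, st = frames(arr, arr * 1.0)
        gs = gistic_scores(sm, st, "gain", n_boot=200, seed=0)
        assert significant_regions(gs, probe_meta(30), alpha=0.0) == []

    def test_separated_runs_stay_separate(self):
        arr = np.zeros((10, 60), dtype=int)
        arr[:8, 10:20] = 1
        arr[:8, 40:50] = 1
        sm, st = frames(arr, arr * 1.0)
        gs = gistic_scores(sm, st, "gain", n_boot=500, seed=0)
        regions = significant_regions(gs, probe_meta(60))
        assert len(regions) == 2

    def test_regions_split_at_chromosome_boundaries(self):
        arr = np.zeros((10, 40), dtype=int)
        arr[:9, 15:25] = 1  # straddles the chr1/chr2 boundary at probe 20
        sm, st = frames(arr, arr * 1.0)
        gs = gistic_scores(sm, st, "gain", n_boot=500, seed=0)
        meta = probe_meta(40)
        meta.loc[20:, "chrom"] = "chr2"
        regions = significant_regions(gs, meta)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chr1", "chr2"}


GENE_MAP = pd.DataFrame(
    {"gene": ["GA", "GB"], "chrom": ["chr1", "chr1"],
     "start_probe": [5, 20], "end_probe": [10, 22]}
)


class TestRecurrentGenes:
    def test_planted_amplification_frequency(self, rng):
        n = 100
        arr = np.zeros((n, 30), dtype=int)
        carriers = rng.random(n) < 0.29
        arr[np.ix_(carriers, np.arange(5, 10))] = 2
        states = pd.DataFrame(arr, columns=[f"P{i}" for i in range(30)])
        res = recurrent_genes(states, GENE_MAP, level="amp", min_freq=0.10)
        row = res[res["gene"] == "GA"]
        assert len(row) == 1
        # binomial tolerance around the planted 29%
        assert row["frequency"].iloc[0] == pytest.approx(0.29, abs=0.12)

    def test_impossible_frequency_empty(self, rng):
        arr = rng.integers(-2, 3, (10, 30))
        states = pd.DataFrame(arr, columns=[f"P{i}" for i in range(30)])
        assert recurrent_genes(states, GENE_MAP, "gain", min_freq=1.01).empty

    def test_zero_threshold_returns_all_touched_genes(self):
        arr = np.zeros((4, 30), dtype=int)
        arr[0, 6] = 1
        states = pd.DataFrame(arr, columns=[f"P{i}" for i in range(30)])
        res = recurrent_genes(states, GENE_MAP, "gain", min_freq=0.0)
        assert list(res["gene"]) == ["GA"]
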