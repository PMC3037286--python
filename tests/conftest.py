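import numpy as np
import pytest

from cnax.pipeline import analyze_cohort, demo_fixture


@pytest.fixture(scope="session")
def demo_cohort():
    """The packaged small demo cohort (deterministic, seed 0)."""
    return demo_fixture(seed=0)


@pytest.fixture(scope="session")
def demo_analysis(demo_cohort):
    """The demo cohort pushed through segment -> call -> differential ->
    candidate filter once per test session."""
    return analyze_cohort(demo_cohort, cbs_n_perm=128, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def exhaustive_breakpoints(x: np.ndarray, k: int, min_width: int = 5) -> list[int]:
    """Independent segmentation oracle: the best k-breakpoint model by
    exhaustive search, minimizing total within-segment sum of squares
    (equivalently maximizing between-segment variance). Used to check CBS
    on small, high signal-to-noise tracks."""
    n = len(x)
    s = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a, b):
        tot = s[b] - s[a]
        return (s2[b] - s2[a]) - tot * tot / (b - a)

    if k == 0:
        return []
    best, best_bp = np.inf, []
    if k == 1:
        for b in range(min_width, n - min_width + 1):
            v = sse(0, b) + sse(b, n)
            if v < best:
                best, best_bp = v, [b]
        return best_bp
    if k == 2:
        for b1 in range(min_width, n - 2 * min_width + 1):
            left = sse(0, b1)
            for b2 in range(b1 + min_width, n - min_width + 1):
                v = left + sse(b1, b2) + sse(b2, n)
                if v < best:
                    best, best_bp = v, [b1, b2]
        return best_bp
    raise ValueError("oracle supports k <= 2")
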