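"""The inferential tests used on pipeline outputs.

Two-sample Kolmogorov--Smirnov for shape distributions, Watson's two-sample
U² test of homogeneity for axial angle distributions (angles are doubled to
the full circle first, the standard axial treatment), and Kruskal--Wallis
followed by pairwise two-sided Wilcoxon rank-sum tests with Bonferroni
adjustment for the fusion-duration comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)


def ks_two_sample(a, b) -> TestResult:
    """Two-sided two-sample Kolmogorov--Smirnov test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "two-sample KS", (a.size, b.size))


def watson_u2(a: np.ndarray, b: np.ndarray) -> float:
    """Watson's two-sample U² statistic on circular data (radians).

    Ties are handled by averaging the empirical CDF step over tied pooled
    values (mid-rank convention).
    """
    n, m = len(a), len(b)
    N = n + m
    pooled = np.concatenate([a % (2 * np.pi), b % (2 * np.pi)])
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])
    order = np.argsort(pooled, kind="mergesort")
    pooled = pooled[order]
    is_a = is_a[order]
    cdf_a = np.cumsum(is_a) / n
    cdf_b = np.cumsum(~is_a) / m
    d = cdf_a - cdf_b
    # collapse ties: evaluate d only after the last of each tied block
    last_of_block = np.r_[pooled[1:] != pooled[:-1], True]
    d = d[last_of_block]
    weights = np.diff(np.r_[0, np.flatnonzero(last_of_block) + 1])
    dbar = np.sum(d * weights) / N
    return float(n * m / N ** 2 * np.sum(weights * (d - dbar) ** 2))


def _watson_p_asymptotic(u2: float, terms: int = 20) -> float:
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k ** 2
                                                * np.pi ** 2 * u2))
    return float(min(1.0, max(0.0, p)))


def watson_two_sample(angles_a, angles_b, axial: bool = True,
                      degrees: bool = True, method: str = "permutation",
                      n_permutations: int = 999,
                      seed: int | None = 0) -> TestResult:
    """Watson's two-sample test of homogeneity on (axial) angle samples.

    Axial angles are doubled to the full circle before testing.  ``method``
    is "permutation" (default; random relabelling, seeded) or "asymptotic"
    (the large-sample series for the U² null distribution).
    """
    a = np.asarray(angles_a, float)
    b = np.asarray(angles_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Watson test requires n >= 2 per sample")
    if degrees:
        a, b = np.radians(a), np.radians(b)
    if axial:
        a, b = 2 * a, 2 * b
    u2 = watson_u2(a, b)
    if method == "asymptotic":
        p = _watson_p_asymptotic(u2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 1
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if watson_u2(perm[:a.size], perm[a.size:]) >= u2:
                count += 1
        p = count / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(u2, float(p), f"Watson two-sample U2 ({method})",
                      (a.size, b.size))


def kruskal_then_pairwise(groups, labels=None) -> dict:
    """Kruskal--Wallis omnibus test plus Bonferroni-adjusted pairwise
    two-sided Wilcoxon rank-sum comparisons.

    Returns {"omnibus": TestResult, "pairwise": [TestResult, ...]} where each
    pairwise result's ``extra`` records the group pair and the raw p value.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    H, p = sps.kruskal(*groups)
    omnibus = TestResult(float(H), float(p), "Kruskal-Wallis",
                         tuple(g.size for g in groups))
    pairs = [(i, j) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    k = len(pairs)
    pairwise = []
    for i, j in pairs:
        res = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        adj = min(1.0, float(res.pvalue) * k)
        pairwise.append(TestResult(
            float(res.statistic), adj, "Wilcoxon rank-sum",
            (groups[i].size, groups[j].size), adjustment="bonferroni",
            extra={"pair": (labels[i], labels[j]),
                   "p_raw": float(res.pvalue)}))
    return {"omnibus": omnibus, "pairwise": pairwise}
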