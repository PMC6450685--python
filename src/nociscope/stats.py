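"""Statistical kernels implemented from first principles.

The Wilcoxon signed-rank test, Benjamini-Hochberg step-up, and Spearman
correlation are written out explicitly (rather than delegated to scipy or
statsmodels) because they are load-bearing for the decoder-significance and
responder analyses; the reference libraries serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "midranks",
    "spearman",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float       # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int            # pairs remaining after dropping zero differences
    exact: bool
    all_zero: bool = False


def midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties receiving the average (mid) rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_sf(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(W+ >= w) under the signed-rank null by dynamic programming.

    Works on ranks doubled to integers so midranks (x.5) are exact.  Each of
    the 2^n sign patterns is equally likely; the DP convolves the rank-sum
    distribution one pair at a time.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w = max(0, int(np.ceil(doubled_w - 1e-9)))
    return float(dist[w:].sum())


def wilcoxon_signed_rank(differences: np.ndarray, sided: str = "one") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical Wilcoxon convention).  For
    n <= 25 the null distribution of W+ is enumerated exactly (tie-aware via
    doubled midranks); beyond that a normal approximation with tie and
    continuity corrections is used.  ``sided='one'`` tests for positive
    location (W+ large).
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be 1-D")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, exact=True,
                              all_zero=True)
    ranks = midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0

    if n <= _EXACT_N_MAX:
        doubled = np.round(2.0 * ranks).astype(int)
        p_hi = _exact_sf(doubled, int(round(2 * w_plus)))
        if sided == "one":
            p = p_hi
        else:
            # P(W+ <= w) by symmetry of the full distribution around total/2
            p_lo = _exact_sf(doubled, int(round(2 * (total - w_plus))))
            p = min(1.0, 2.0 * min(p_hi, p_lo))
        return WilcoxonResult(w_plus, float(min(p, 1.0)), n, exact=True)

    mean = total / 2.0
    # tie correction on the variance, as for the large-sample signed-rank test
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = np.sqrt(var)
    from scipy.stats import norm

    z = (w_plus - mean - 0.5) / sd  # continuity-corrected, upper tail
    if sided == "one":
        p = float(norm.sf(z))
    else:
        z2 = (abs(w_plus - mean) - 0.5) / sd
        p = float(2.0 * norm.sf(z2))
    return WilcoxonResult(w_plus, float(min(p, 1.0)), n, exact=False)


def benjamini_hochberg(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values).  Adjusted values are the
    monotone cumulative minimum of m*p/i taken from the largest rank down.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    # step-up: largest i with p(i) <= i*q/m; reject 1..i
    passing = np.nonzero(ranked <= np.arange(1, m + 1) * q / m)[0]
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[:passing[-1] + 1] = True
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adjusted_sorted
    return reject, adjusted


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = midranks(x), midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def mean_sem(values) -> tuple[float, float, int]:
    """Mean, standard error, and n for a 1-D sample (ddof=1 SEM)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        return float("nan"), float("nan"), 0
    if n == 1:
        return float(v[0]), float("nan"), 1
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)), n
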