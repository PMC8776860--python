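"""Paired-comparison and correlation statistics for the fold-change stage.

* Wilcoxon matched-pairs signed-rank test with an exact two-sided p-value
  for small samples (the 11-patient clinical regime) and a tie-corrected
  normal approximation beyond.
* Spearman rank correlation with a t-approximation p-value by default and
  an exact permutation option at very small n.
* Quadratic least-squares fit with a pointwise 95% confidence band (the
  scatter-plot companion to the correlations).

The exact Wilcoxon null distribution is built by subset-sum convolution
over the (mid)ranks of the absolute differences, which is equivalent to
enumerating all 2^n sign assignments and also covers tied ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

from ._errors import DegenerateStatisticError, ValidationError

_EXACT_LIMIT = 25  # exact signed-rank enumeration up to this many nonzero diffs


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float          # W+ = rank sum of positive differences
    p_value: float
    n_used: int               # pairs remaining after zero differences dropped
    method: str               # "exact" or "approximation"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str               # "t-approximation" or "exact-permutation"


@dataclass(frozen=True)
class QuadFit:
    coefficients: tuple[float, float, float]   # intercept, linear, quadratic
    se: tuple[float, float, float]
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df_resid: int


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled rank-sum value.

    ``ranks2`` holds midranks multiplied by 2 (integers even with ties).
    Entry s of the result counts sign vectors whose positive-rank sum
    (doubled) equals s; the total is 2^n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(pre, post) -> PairedTestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test of post vs pre.

    Zero differences are discarded (classic convention). With at most 25
    nonzero differences the p-value is exact over all sign assignments
    (midranks for tied magnitudes); otherwise a normal approximation with
    tie correction is used. The statistic is W+, the rank sum of positive
    (post - pre) differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateStatisticError(
            "all paired differences are zero; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= _EXACT_LIMIT:
        ranks2 = np.rint(ranks * 2).astype(int)
        pmf = _signed_rank_pmf(ranks2)
        w2 = int(round(w_plus * 2))
        total = 2.0 ** n
        cdf = pmf[: w2 + 1].sum() / total
        sf = pmf[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return PairedTestResult(w_plus, p, n, "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return PairedTestResult(w_plus, min(1.0, p), n, "approximation")


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _drop_missing(x, y):
    x = np.asarray(
        [np.nan if v is None else float(v) for v in x], dtype=float)
    y = np.asarray(
        [np.nan if v is None else float(v) for v in y], dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int((~keep).sum())


def spearman(x, y, *, exact: bool = False) -> SpearmanResult:
    """Spearman rank correlation with pairwise removal of flagged-missing
    entries (None/NaN).

    ``rho`` is the Pearson correlation of midranks. The two-sided p-value
    uses the t approximation by default; ``exact=True`` enumerates all rank
    permutations (n <= 10 only).
    """
    x, y, n_dropped = _drop_missing(x, y)
    n = len(x)
    if n < 3:
        raise ValidationError(
            f"need >= 3 complete pairs after dropping {n_dropped} missing")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("constant input: Spearman rho undefined")

    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if exact:
        if n > 10:
            raise ValidationError("exact permutation p limited to n <= 10")
        # Enumerate rho over all pairings of the observed rank vectors.
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rho)
        hits = 0
        count = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.dot(rx_c[list(perm)], ry_c)) / denom
            hits += abs(r) >= obs - 1e-12
            count += 1
        return SpearmanResult(rho, hits / count, n, "exact-permutation")

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, min(1.0, float(p)), n, "t-approximation")


# ---------------------------------------------------------------------------
# quadratic regression with confidence band
# ---------------------------------------------------------------------------

def quadratic_fit_ci(x, y, grid=None, alpha: float = 0.05) -> QuadFit:
    """Least-squares fit of y on (1, x, x^2) with a pointwise CI band.

    The band is the t-based confidence interval for the conditional mean on
    ``grid`` (default: 100 points spanning the observed x-range), with
    n - 3 residual degrees of freedom.
    """
    x, y, _ = _drop_missing(x, y)
    n = len(x)
    if n < 4:
        raise ValidationError("quadratic fit needs >= 4 points")
    X = np.column_stack([np.ones(n), x, x ** 2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("collinear design: quadratic fit undefined")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)

    res = sm.OLS(y, X).fit()
    Xg = np.column_stack([np.ones(len(grid)), grid, grid ** 2])
    pred = res.get_prediction(Xg)
    ci = pred.conf_int(alpha=alpha)
    return QuadFit(
        coefficients=tuple(res.params),
        se=tuple(res.bse),
        grid=grid,
        fitted=pred.predicted_mean,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        df_resid=int(res.df_resid),
    )
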