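"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or dense
numerical integration, sharing no code path with the library
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


# --- motif scanners -------------------------------------------------------

def g4_present_brute(seq: str) -> bool:
    """Four G-tracts (GG or GGG) chained by 1-7 nt loops, found by
    explicit enumeration of tract start positions."""
    n = len(seq)
    for tract in (2, 3):
        g = "G" * tract
        starts = {i for i in range(n - tract + 1) if seq[i : i + tract] == g}

        def chain(pos: int, remaining: int) -> bool:
            if remaining == 0:
                return True
            for loop in range(1, 8):
                nxt = pos + tract + loop
                if nxt in starts and chain(nxt, remaining - 1):
                    return True
            return False

        if any(chain(p, 3) for p in starts):
            return True
    return False


def paired_ggagg_brute(seq: str) -> bool:
    """Two GGAGG occurrences separated by a 4-10 nt linker, by pairwise
    enumeration of occurrence positions."""
    hits = [i for i in range(len(seq) - 4) if seq[i : i + 5] == "GGAGG"]
    return any(4 <= q - (p + 5) <= 10 for p in hits for q in hits if q > p)


def ggc_repeat_brute(seq: str) -> bool:
    """GC(GGC){3}G is the literal 12-mer GCGGCGGCGGCG."""
    return "GCGGCGGCGGCG" in seq


# --- secondary structure --------------------------------------------------

_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str, min_hairpin: int = 3) -> int:
    """Maximum canonical pairing by explicit enumeration of every
    non-crossing structure (no memoization, no branch-and-bound);
    tractable for sequences of ~14 nt."""

    def structures(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        for rest in structures(i + 1, j):  # i unpaired
            yield rest
        for k in range(i + min_hairpin + 1, j):
            if (seq[i], seq[k]) in _CANONICAL:
                for left in structures(i + 1, k):
                    for right in structures(k + 1, j):
                        yield left | right | {(i, k)}

    return max(len(s) for s in structures(0, len(seq)))


# --- marginal likelihood --------------------------------------------------

def logml_grid_2d(
    y: np.ndarray,
    s: np.ndarray,
    x: np.ndarray,
    tau: float,
    sigma_scale: float = 1.0,
    n_beta: int = 20001,
    n_sigma: int = 2401,
    beta_half_width: float = 8.0,
    sigma_max: float = 6.0,
) -> float:
    """Dense grid integration of the observation-model evidence over
    (coefficient, residual SD) for a one-column design.

    The residual SD is gridded as sigma = t^2 (quadratic stretch, fine
    resolution near zero where the integrand varies fastest); the
    Gaussian log-likelihood is quadratic in the coefficient, so each
    grid column is evaluated from its exact expansion
    ``-(A - 2 b B + b^2 C)/2`` — pure grid summation, no conjugacy
    shortcut."""
    beta = np.linspace(-beta_half_width * tau, beta_half_width * tau, n_beta)
    t = np.linspace(0.0, np.sqrt(sigma_max), n_sigma)
    sigma = t**2
    dt = t[1] - t[0]
    w = 2.0 * t * dt  # d sigma per cell
    w[0] = w[1] / 4.0  # origin half-cell under the t^2 measure
    d = s[None, :] ** 2 + sigma[:, None] ** 2  # (n_sigma, n)
    base = -0.5 * np.sum(np.log(2 * np.pi * d), axis=1)  # (n_sigma,)
    A = np.sum(y[None, :] ** 2 / d, axis=1)
    B = np.sum(x[None, :] * y[None, :] / d, axis=1)
    C = np.sum(x[None, :] ** 2 / d, axis=1)
    lp_beta = norm.logpdf(beta, 0.0, tau)
    lp_sigma = norm.logpdf(sigma, 0.0, sigma_scale) + np.log(2.0)
    col_lse = np.empty(n_sigma)
    for j in range(n_sigma):
        v = base[j] - 0.5 * (A[j] - 2.0 * beta * B[j] + beta**2 * C[j])
        col_lse[j] = logsumexp(v + lp_beta) + lp_sigma[j] + np.log(w[j])
    return float(logsumexp(col_lse) + np.log(beta[1] - beta[0]))


def logml_conjugate(y: np.ndarray, s: np.ndarray, X: np.ndarray, tau: np.ndarray, sigma: float) -> float:
    """Closed-form Gaussian evidence at fixed residual SD: the marginal
    of y is N(0, diag(s^2 + sigma^2) + X diag(tau^2) X')."""
    from scipy.stats import multivariate_normal

    cov = np.diag(s**2 + sigma**2) + X @ np.diag(np.asarray(tau) ** 2) @ X.T
    return float(multivariate_normal(mean=np.zeros(len(y)), cov=cov).logpdf(y))


# --- classical statistics -------------------------------------------------

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact rational enumeration of the
    hypergeometric support at fixed margins."""
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)
    nums = [
        comb(n1, x) * comb(n2, k - x) for x in range(max(0, k - n2), min(k, n1) + 1)
    ]
    obs = comb(n1, a) * comb(n2, c)
    return Fraction(sum(v for v in nums if v <= obs), denom)


def ks_exact_permutation(a, b) -> tuple[float, float]:
    """Two-sample KS statistic and exact permutation p by enumerating
    every assignment of the pooled sample (tie-free data)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n, m = len(a), len(b)

    def d_stat(xs, ys):
        xs, ys = sorted(xs), sorted(ys)
        grid = sorted(set(xs + ys))
        best = 0.0
        for g in grid:
            fa = sum(x <= g for x in xs) / len(xs)
            fb = sum(y <= g for y in ys) / len(ys)
            best = max(best, abs(fa - fb))
        return best

    d_obs = d_stat(a, b)
    count = total = 0
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        total += 1
        if d_stat(xs, ys) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total
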