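"""Resampling tests: paired sign-flip permutation tests and the permuted
Pearson correlation (Mantel-equivalent for paired distance/similarity vectors).

Conventions
-----------
Two-tailed p-values are defined through the absolute statistic (the nulls here
are symmetric).  Ties count as extreme (>=).  In Monte-Carlo mode p uses the
add-one correction (b + 1) / (m + 1), which guarantees p > 0; in exhaustive
mode p = b / m with the identity permutation included among the m.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

EXHAUSTIVE_CAP = 2**20


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    n_perm: int
    n_extreme: int
    p_two_tailed: float
    mode: str  # "exhaustive" | "monte_carlo"
    seed: int | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_perm": self.n_perm,
            "n_extreme": self.n_extreme,
            "p_two_tailed": self.p_two_tailed,
            "mode": self.mode,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign assignments as a (2^n, n) array of +/-1 (identity first)."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits


def paired_permutation_test(
    pairs,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    mode: str = "auto",
) -> PermutationResult:
    """Exact paired permutation test on the mean within-pair difference.

    The null swaps the two values within each pair independently, which is
    equivalent to flipping the sign of each difference.  All 2^n assignments
    are enumerated when 2^n <= exhaustive_cap; otherwise ``n_perm`` random
    sign vectors are drawn (Monte-Carlo mode) with the stated seed.
    ``mode`` forces "exhaustive" or "monte_carlo"; "auto" applies the cap.
    """
    if mode not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of paired values")
    n = pairs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("paired values must be finite")
    exhaustive = (mode == "exhaustive"
                  or (mode == "auto" and 2**n <= exhaustive_cap))
    if exhaustive and 2**n > exhaustive_cap:
        raise ValueError("exhaustive enumeration exceeds exhaustive_cap")

    d = pairs[:, 0] - pairs[:, 1]
    observed = float(d.mean())
    if np.all(d == 0):
        m = 2**n if exhaustive else n_perm
        return PermutationResult(0.0, m, m, 1.0,
                                 "exhaustive" if exhaustive else "monte_carlo",
                                 seed, degenerate=True)

    tol = 1e-12 * max(1.0, abs(observed))
    if exhaustive:
        stats = _sign_matrix(n) @ d / n
        n_extreme = int(np.sum(np.abs(stats) >= abs(observed) - tol))
        m = 2**n
        return PermutationResult(observed, m, n_extreme, n_extreme / m,
                                 "exhaustive", None)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    stats = signs @ d / n
    n_extreme = int(np.sum(np.abs(stats) >= abs(observed) - tol))
    p = (n_extreme + 1) / (n_perm + 1)
    return PermutationResult(observed, n_perm, n_extreme, p, "monte_carlo", seed)


def pearson_r(x, y) -> float:
    """Bravais-Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def permuted_correlation_test(
    x,
    y,
    n_perm: int = 1_000,
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    mode: str = "auto",
) -> PermutationResult:
    """Significance of Pearson r by randomly permuting y against fixed x.

    For paired vectors of distances or similarities this is the vector
    equivalent of a Mantel test.  All n! orderings are enumerated when
    n! <= exhaustive_cap (or when ``mode`` forces it).
    """
    if mode not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    observed = pearson_r(x, y)  # validates finiteness and non-constancy

    # r against every reordering of y reduces to a dot product with
    # standardized vectors: permutation preserves y's mean and variance.
    xc = x - x.mean()
    xs = xc / np.sqrt(np.sum(xc**2))
    yc = y - y.mean()
    ynorm = np.sqrt(np.sum(yc**2))

    exhaustive = (mode == "exhaustive"
                  or (mode == "auto" and math.factorial(n) <= exhaustive_cap))
    if exhaustive and math.factorial(n) > exhaustive_cap:
        raise ValueError("exhaustive enumeration exceeds exhaustive_cap")

    tol = 1e-12
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        rs = (yc[perms] @ xs) / ynorm
        n_extreme = int(np.sum(np.abs(rs) >= abs(observed) - tol))
        m = len(perms)
        return PermutationResult(observed, m, n_extreme, n_extreme / m,
                                 "exhaustive", None)
    rng = np.random.default_rng(seed)
    yp = rng.permuted(np.broadcast_to(yc, (n_perm, n)).copy(), axis=1)
    rs = (yp @ xs) / ynorm
    n_extreme = int(np.sum(np.abs(rs) >= abs(observed) - tol))
    p = (n_extreme + 1) / (n_perm + 1)
    return PermutationResult(observed, n_perm, n_extreme, p, "monte_carlo", seed)
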