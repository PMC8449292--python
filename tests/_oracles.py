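"""Independent brute-force oracles the implementation is checked against.

Everything here is written from first principles (exhaustive scans, closed
forms, grid searches) and never calls into rdocpheno's computational paths.
"""

from __future__ import annotations

import numpy as np


def oracle_scores(tokens: list[str], domain_terms: dict[str, set[str]]) -> dict[str, float]:
    """Presence-fraction scores by exhaustive contiguous n-gram scan."""
    out = {}
    for domain, terms in domain_terms.items():
        hits = 0
        for term in terms:
            tt = term.split(" ")
            k = len(tt)
            found = any(tokens[i : i + k] == tt for i in range(len(tokens) - k + 1))
            hits += found
        out[domain] = hits / len(terms)
    return out


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS: beta = (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def crossproduct_or(n11: int, n10: int, n01: int, n00: int) -> float:
    """2x2 odds ratio (exposed long, exposed short, unexposed long, unexposed short)."""
    return (n11 * n00) / (n10 * n01)


def efron_loglik(beta: float, times: np.ndarray, x: np.ndarray) -> float:
    """Efron partial log-likelihood for one covariate, all events observed."""
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(times):
        dead = times == t
        at_risk = times >= t
        d = int(dead.sum())
        sum_dead = theta[dead].sum()
        sum_risk = theta[at_risk].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return ll


def efron_grid_argmax(times: np.ndarray, x: np.ndarray, lo: float = -5.0, hi: float = 5.0,
                      step: float = 1e-3) -> float:
    """Grid-searched maximizer of the Efron partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = [efron_loglik(b, times, x) for b in grid]
    return float(grid[int(np.argmax(lls))])
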