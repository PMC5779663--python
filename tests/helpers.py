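"""Independent oracles and shared property checks.

Everything here deliberately avoids the code paths it is used to verify:
the first-split oracle enumerates labelings and thresholds by brute force
with its own statistic arithmetic (hypergeometric moments via scipy), and
the extinction oracle is the closed-form branching-process formula.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

from bearpva.design_space import DemographicParams
from bearpva.projection import SimulationConfig, simulate_batch


def exact_linear_p(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force two-sided permutation p-value for T = sum x[y==1]."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = int(np.sum(y == 1))
    obs = x[np.asarray(y) == 1].sum()
    mean = m * x.mean()
    count = total = 0
    for subset in combinations(range(n), m):
        total += 1
        if abs(x[list(subset)].sum() - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def brute_force_split_z(x: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """|z| of the left/right two-sample split, hypergeometric moments from scipy."""
    n = len(x)
    m = int(np.sum(y == 1))
    left = x <= threshold
    nl = int(left.sum())
    if nl == 0 or nl == n or m == 0 or m == n:
        return 0.0
    k = int(np.sum(y[left] == 1))
    dist = hypergeom(M=n, n=m, N=nl)
    return abs((k - dist.mean()) / math.sqrt(dist.var()))


def oracle_first_split(X, y, minbucket: int = 1):
    """Exhaustive (variable, threshold) choice for the root split.

    Variable: minimum exact permutation p over all predictors (ties by
    column order). Threshold: maximal brute-force |z| over every feasible
    observed value, smallest threshold on ties.
    """
    best_var, best_p = None, np.inf
    for var in X.columns:
        p = exact_linear_p(X[var].to_numpy(), y)
        if p < best_p:
            best_var, best_p = var, p
    x = X[best_var].to_numpy()
    n = len(x)
    best_thr, best_z = None, -np.inf
    for thr in sorted(np.unique(x)):
        nl = int(np.sum(x <= thr))
        if nl < minbucket or n - nl < minbucket:
            continue
        z = brute_force_split_z(x, y, thr)
        if z > best_z + 1e-12:
            best_thr, best_z = thr, z
    return best_var, best_p, best_thr


def pure_death_extinction_prob(p_survive: float, t: int, k: int) -> float:
    """Closed form: with no recruitment, P(extinct by year t | N0 = k) = (1 - p^t)^k."""
    return (1.0 - p_survive**t) ** k


def simulate_pure_death_extinct_fraction(
    p_survive: float, t: int, k: int, n_traj: int, seed: int
) -> float:
    """Monte-Carlo extinct fraction from the projection engine, recruitment off."""
    logit_p = math.log(p_survive / (1 - p_survive))
    params = DemographicParams(
        mu_phi=logit_p, sigma_phi=0.0, beta0f=-40.0, beta1f=0.0, sigma_f=0.0
    )
    config = SimulationConfig(N0=k, T=t, n_traj=n_traj)
    N, _, _ = simulate_batch(params, config, np.random.default_rng(seed))
    return float(np.mean(N[:, t] == 0))


def three_se(p: float, n: int) -> float:
    return 3.0 * math.sqrt(p * (1.0 - p) / n)
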