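"""Independent oracles for the test suite.

These deliberately avoid the implementation's algorithms: the relationship
matrix is rebuilt by brute-force enumeration of connecting paths (Wright's
method), and the animal-model likelihood is evaluated exactly on a dense
multivariate-normal grid over h^2. They are slow and only suitable for tiny
problems, which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from owlfid.pedigree import Individual, Pedigree, validate_pedigree


def path_counting_relationship(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by Wright's path counting.

    a_ij (i != j) sums (1/2)^(n_i + n_j) (1 + F_k) over every pair of
    ancestral paths from i and j that meet at a common ancestor k and share
    no other individual; a_ii = 1 + F_i with F_i the kinship of the parents,
    obtained from the same path enumeration.
    """
    n = len(ped)
    paths: list[list[tuple[int, frozenset, int]]] = []
    for i in range(n):
        out = [(i, frozenset([i]), 0)]
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                out.extend(
                    (anc, nodes | {i}, edges + 1) for anc, nodes, edges in paths[p]
                )
        paths.append(out)

    F = np.zeros(n)

    def rel(i: int, j: int) -> float:
        if i == j:
            return 1.0 + F[i]
        total = 0.0
        for anc1, nodes1, e1 in paths[i]:
            for anc2, nodes2, e2 in paths[j]:
                if anc1 == anc2 and len(nodes1 & nodes2) == 1:
                    total += 0.5 ** (e1 + e2) * (1.0 + F[anc1])
        return total

    for i in range(n):  # topological order: ancestors' F ready before use
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            F[i] = 0.5 * rel(s, d)

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = rel(i, j)
    return A


def random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.35,
                    p_single_parent: float = 0.15) -> Pedigree:
    """Random valid pedigree with full sibs, half sibs and occasional inbreeding."""
    records: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    for k in range(n):
        sex = "female" if rng.random() < 0.5 else "male"
        sire = dam = None
        if k >= 2 and males and females and rng.random() > p_founder:
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            if rng.random() < p_single_parent:
                if rng.random() < 0.5:
                    sire = None
                else:
                    dam = None
        ident = f"R{k:03d}"
        records.append(Individual(id=ident, sire=sire, dam=dam, sex=sex))
        (females if sex == "female" else males).append(ident)
    return validate_pedigree(records)


def h2_profile_mle(y: np.ndarray, X: np.ndarray, A: np.ndarray,
                   grid: np.ndarray | None = None) -> float:
    """Exact multivariate-normal maximum-likelihood h^2 on a dense grid.

    For each h^2 the covariance is sigma2_P (h^2 A + (1 - h^2) I); beta is the
    GLS estimate and sigma2_P is profiled out in closed form.
    """
    if grid is None:
        grid = np.arange(0.01, 1.00, 0.01)
    n = len(y)
    best_ll, best_h2 = -np.inf, None
    for h2 in grid:
        V0 = h2 * A + (1.0 - h2) * np.eye(n)
        cf = linalg.cho_factor(V0)
        Vi_y = linalg.cho_solve(cf, y)
        Vi_X = linalg.cho_solve(cf, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        r = y - X @ beta
        s2 = float(r @ linalg.cho_solve(cf, r)) / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (n * np.log(s2) + logdet)
        if ll > best_ll:
            best_ll, best_h2 = ll, float(h2)
    return best_h2


def beta_hpd_analytic(a: float, b: float, level: float = 0.95) -> tuple[float, float]:
    """Analytic HPD interval of a Beta(a, b) density (a, b > 1) by bisection
    on the density cut height."""
    from scipy import optimize, stats

    dist = stats.beta(a, b)
    mode = (a - 1) / (a + b - 2)

    def mass_at_cut(c: float) -> float:
        lo = optimize.brentq(lambda x: dist.pdf(x) - c, 1e-12, mode)
        hi = optimize.brentq(lambda x: dist.pdf(x) - c, mode, 1 - 1e-12)
        return dist.cdf(hi) - dist.cdf(lo)

    peak = dist.pdf(mode)
    cut = optimize.brentq(lambda c: mass_at_cut(c) - level, 1e-9 * peak, peak * (1 - 1e-9))
    lo = optimize.brentq(lambda x: dist.pdf(x) - cut, 1e-12, mode)
    hi = optimize.brentq(lambda x: dist.pdf(x) - cut, mode, 1 - 1e-12)
    return lo, hi
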