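"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: the restricted
log-likelihood is evaluated densely from its definition, relatedness is
estimated by gene-dropping Monte Carlo, and pedigrees are generated by a
simple random-mating scheme.
"""

from __future__ import annotations

import numpy as np

from kinstats.pedigree import Individual, Pedigree

_LOG2PI = np.log(2 * np.pi)


def dense_reml_loglik(sa: float, se: float, A: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood evaluated directly from its dense definition."""
    n, p = X.shape
    V = sa * A + se * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    M = X.T @ Vinv @ X
    signM, logdetM = np.linalg.slogdet(M)
    if signM <= 0:
        return -np.inf
    P = Vinv - Vinv @ X @ np.linalg.inv(M) @ X.T @ Vinv
    return float(-0.5 * (logdetV + logdetM + y @ P @ y + (n - p) * _LOG2PI))


def grid_search_reml(A, y, X, lo_frac=0.02, hi_frac=2.0, size=50):
    """Brute-force grid over (sigma2_a, sigma2_e) plus local refinement."""
    from scipy.optimize import minimize

    vary = float(np.var(y, ddof=X.shape[1]))
    grid = np.linspace(lo_frac * vary, hi_frac * vary, size)
    best, best_ll = None, -np.inf
    lls = np.empty((size, size))
    for i, sa in enumerate(grid):
        for j, se in enumerate(grid):
            ll = dense_reml_loglik(sa, se, A, y, X)
            lls[i, j] = ll
            if ll > best_ll:
                best, best_ll = (sa, se), ll
    res = minimize(
        lambda th: -dense_reml_loglik(th[0], th[1], A, y, X),
        x0=np.array(best),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    return res.x, -res.fun, lls


def gene_drop_relatedness(ped: Pedigree, n_rep: int, rng: np.random.Generator):
    """Monte-Carlo expected IBD relatedness by dropping founder allele labels.

    Each founder carries two distinct allele labels; each offspring inherits
    one allele of each parent uniformly at random.  The additive relatedness
    a_ij = 2 * kinship is estimated as the mean over replicates of
    (1/2) sum over the four allele comparisons of 1[labels identical].

    Returns (ids, a_hat, a_se): point estimates and Monte-Carlo standard
    errors, both (n x n).
    """
    order = sorted(ped.ids, key=lambda i: (ped.generation[i], i))
    alleles = {}
    label = 0
    for iid in order:
        ind = ped[iid]
        if ind.is_founder:
            alleles[iid] = np.stack(
                [np.full(n_rep, label, dtype=np.int32), np.full(n_rep, label + 1, dtype=np.int32)],
                axis=1,
            )
            label += 2
        else:
            cols = []
            for parent in (ind.father, ind.mother):
                if parent is None:
                    alleles_p = np.stack(
                        [np.full(n_rep, label, dtype=np.int32), np.full(n_rep, label + 1, dtype=np.int32)],
                        axis=1,
                    )
                    label += 2
                else:
                    alleles_p = alleles[parent]
                pick = rng.integers(0, 2, n_rep)
                cols.append(alleles_p[np.arange(n_rep), pick])
            alleles[iid] = np.stack(cols, axis=1)
    n = len(order)
    a_hat = np.zeros((n, n))
    a_se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[order[i]]
        for j in range(i, n):
            aj = alleles[order[j]]
            x = 0.5 * (
                (ai[:, 0] == aj[:, 0]).astype(np.float64)
                + (ai[:, 0] == aj[:, 1])
                + (ai[:, 1] == aj[:, 0])
                + (ai[:, 1] == aj[:, 1])
            )
            a_hat[i, j] = a_hat[j, i] = x.mean()
            a_se[i, j] = a_se[j, i] = x.std(ddof=1) / np.sqrt(n_rep)
    return order, a_hat, a_se


def random_pedigree(rng: np.random.Generator, n_target: int = 15, n_gen: int = 3) -> Pedigree:
    """Random multi-generation pedigree by random mating within generations."""
    inds = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"I{counter:03d}"

    n_found = max(4, n_target // 3)
    males = [new_id() for _ in range(n_found // 2 + 1)]
    females = [new_id() for _ in range(n_found - n_found // 2 + 1)]
    for i in males:
        inds.append(Individual(i, sex="male"))
    for i in females:
        inds.append(Individual(i, sex="female"))
    for _ in range(n_gen - 1):
        next_m, next_f = [], []
        n_children = max(2, (n_target - counter) // max(n_gen - 1, 1))
        for _ in range(n_children):
            if counter >= n_target:
                break
            f = males[rng.integers(len(males))]
            m = females[rng.integers(len(females))]
            cid = new_id()
            if rng.random() < 0.5:
                inds.append(Individual(cid, f, m, "male"))
                next_m.append(cid)
            else:
                inds.append(Individual(cid, f, m, "female"))
                next_f.append(cid)
        males = next_m or males
        females = next_f or females
    return Pedigree(inds)
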