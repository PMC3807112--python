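"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's null-space geometry code path:
flux coupling is decided by linear programming over S·v = 0, matrix ranks
come straight from numpy's SVD-based rank, and the hypergeometric tail is
re-estimated by Monte-Carlo resampling.
"""

import numpy as np
from scipy.optimize import linprog


def lp_flux_ratio_range(S, j, i, bound=1e3):
    """(min, max) of v_i over {v : S·v = 0, v_j = 1, |v| ≤ bound}.

    Returns None when fixing v_j = 1 is infeasible (reaction j blocked).
    """
    n = S.shape[1]
    bounds = [(-bound, bound)] * n
    bounds[j] = (1.0, 1.0)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[i] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if not res.success:
            return None
        out.append(sign * res.fun)
    return min(out), max(out)


def lp_fully_coupled(S, i, j, tol=1e-6):
    """True iff v_i/v_j is a fixed nonzero ratio in every steady state."""
    if i == j:
        return True
    rng = lp_flux_ratio_range(S, j, i)
    if rng is None:
        return False
    lo, hi = rng
    return (hi - lo) < tol and abs(lo) > tol


def lp_coupling_classes(S, tol=1e-6):
    """Full-coupling partition of non-blocked reactions, by pairwise LPs."""
    n = S.shape[1]
    blocked = [lp_flux_ratio_range(S, j, j) is None for j in range(n)]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    alive = [j for j in range(n) if not blocked[j]]
    for a in range(len(alive)):
        for b in range(a + 1, len(alive)):
            i, j = alive[a], alive[b]
            if find(i) != find(j) and lp_fully_coupled(S, i, j, tol=tol):
                parent[find(i)] = find(j)
    classes = {}
    for j in alive:
        classes.setdefault(find(j), set()).add(j)
    return sorted((frozenset(c) for c in classes.values()),
                  key=lambda c: (-len(c), min(c)))


def svd_rank(S, rtol=1e-9):
    """Rank from singular values, zeroing those ≤ rtol·σ_max."""
    if S.size == 0:
        return 0
    sv = np.linalg.svd(np.asarray(S, dtype=float), compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


def mc_hypergeom_tail(n_universe, n_a, n_b, n_overlap, n_draws=10_000, seed=0):
    """Monte-Carlo estimate of P[|A ∩ B| ≥ n_overlap] for random fixed-size sets."""
    rng = np.random.default_rng(seed)
    marked = np.zeros(n_universe, dtype=bool)
    marked[:n_a] = True
    hits = 0
    for _ in range(n_draws):
        draw = rng.choice(n_universe, size=n_b, replace=False)
        if marked[draw].sum() >= n_overlap:
            hits += 1
    return hits / n_draws
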