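"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own EM/semantics code paths: the
grid oracle maximises the same observed-data likelihood by brute profile
search over a p grid, and the transition checker re-derives the allowed
output set directly from the relation definitions.
"""

import numpy as np


def hamming_matrix(nbits: int) -> np.ndarray:
    m = 2**nbits
    a = np.arange(m)
    xor = a[:, None] ^ a[None, :]
    d = np.zeros_like(xor)
    while xor.any():
        d += xor & 1
        xor = xor >> 1
    return d.astype(float)


def grid_profile_pscore(
    counts,
    forbidden: int,
    step: float = 1e-3,
    inner: int = 20000,
    tol: float = 1e-13,
) -> tuple[float, float]:
    """Profile-likelihood grid search for the constrained flip-noise MLE.

    For every p on [0, 0.5) the cell probabilities q (with the forbidden
    cell fixed at zero) are fitted by an inner mixture-weight EM; the
    returned p is the grid argmax of the profiled log-likelihood.  All grid
    points are iterated as one vectorised batch.
    """
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    M = counts.shape[0]
    nbits = int(np.log2(M))
    d = hamming_matrix(nbits)
    grid = np.arange(0.0, 0.5, step)
    T_all = grid[:, None, None] ** d[None] * (1 - grid[:, None, None]) ** (
        nbits - d[None]
    )
    q = np.full((len(grid), M), 1.0 / M)
    q[:, forbidden] = 0.0
    q /= q.sum(axis=1, keepdims=True)
    obs = counts > 0
    ll_final = np.full(len(grid), -np.inf)
    active = np.arange(len(grid))
    T = T_all
    ll_prev = np.full(len(grid), -np.inf)
    check_every = 50
    for it in range(1, inner + 1):
        J = q[:, :, None] * T
        r = J.sum(axis=1)
        r_safe = np.where(r > 0, r, 1.0)
        bad = (r[:, obs] <= 0).any(axis=1)
        ll = np.where(bad, -np.inf, (counts[obs] * np.log(r_safe[:, obs])).sum(axis=1))
        ll_final[active] = ll
        W = J * (counts / r_safe)[:, None, :]
        q = W.sum(axis=2) / N
        q[:, forbidden] = 0.0
        s = q.sum(axis=1, keepdims=True)
        q = np.where(s > 0, q / np.where(s > 0, s, 1.0), q)
        if it % check_every == 0:
            stuck = np.isneginf(ll) & np.isneginf(ll_prev)
            with np.errstate(invalid="ignore"):
                gain = np.where(stuck, 0.0, ll - ll_prev)
            ref = np.abs(np.where(np.isfinite(ll_prev), ll_prev, 0.0)) + 1.0
            keep = ~(stuck | (np.abs(gain) < tol * check_every * ref))
            if not keep.any():
                break
            # freeze converged grid points; keep iterating the rest
            active = active[keep]
            q = q[keep]
            T = T[keep]
            ll_prev = ll[keep]
    best = int(np.argmax(ll_final))
    return float(grid[best]), float(ll_final[best])


def allowed_outputs_brute(net, x) -> set:
    """Re-derive the allowed next-step states from first principles.

    Enumerates all 2^n candidate outputs and keeps those violating no
    relation: similarity pins the target to f(x); f > target rules out
    target=1 when f(x)=0; f > dual rules out target=0 when f(x)=0.
    """
    from itertools import product

    allowed = set()
    for y in product((0, 1), repeat=net.n):
        ok = True
        for rel in net.relations:
            fx = rel.func(x)
            yi = y[rel.target - 1]
            if rel.rtype.value == "similar" and yi != fx:
                ok = False
            elif rel.rtype.value == "prereq_target" and fx == 0 and yi == 1:
                ok = False
            elif rel.rtype.value == "prereq_dual" and fx == 0 and yi == 0:
                ok = False
        if ok:
            allowed.add(y)
    return allowed
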