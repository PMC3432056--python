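"""EM estimation of the misclassification probability: the p-score.

With flip noise the structural zeros of a relation are smeared out: a
sample truly in cell ``c`` is observed in cell ``a`` with probability
``p^d (1-p)^(k+1-d)`` where ``d`` is the Hamming distance between the two
cell indices (each of the k input bits and the output bit flips
independently).  The observed table is therefore a multinomial with cell
probabilities ``r_a = sum_c q_c p^d(c,a) (1-p)^(k+1-d(c,a))``.

Each basic relation corresponds to the hypothesis that one cell's *true*
probability is zero.  Fitting ``(q, p)`` by maximum likelihood under that
single constraint yields ``p_hat``, the **p-score** of the hypothesis: the
amount of noise needed to explain the observed counts if the hypothesis
were true.  The smaller the score, the more plausible the relation.

The likelihood is maximised by EM over the latent "splitting counts"
``m_{c,a}`` (how many observations in cell ``a`` truly came from cell
``c``):

* E-step: ``m_{c,a} = n_a q_c p^d (1-p)^(k+1-d) / r_a`` (zero for the
  forbidden cell);
* M-step: ``q_c = sum_a m_{c,a} / N`` and
  ``p = sum_{c,a} d(c,a) m_{c,a} / ((k+1) N)`` — the fraction of latently
  flipped bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .counts import CountTable, build_count_table
from .simulate import TransitionSample

__all__ = ["Hypothesis", "EMResult", "em_fit", "p_score_table", "flip_kernel"]

#: p is restricted to [0, P_MAX]; at and beyond 1/2 the flip model is
#: unidentifiable by symmetry.
P_MAX = 0.5 - 1e-9


@dataclass(frozen=True)
class Hypothesis:
    """One zero-cell hypothesis: the true probability of ``forbidden_cell``
    (flat cell index, output bit lowest) is constrained to zero."""

    forbidden_cell: int


@dataclass(frozen=True)
class EMResult:
    """Fit of the constrained flip-noise multinomial.

    ``p_hat`` is the p-score; ``q_hat`` the estimated true cell
    probabilities (zero at the forbidden cell); ``loglik`` the observed-data
    log-likelihood at the final parameters; ``loglik_path`` its value after
    every iteration (non-decreasing by the EM ascent property).
    """

    p_hat: float
    q_hat: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    loglik_path: np.ndarray


@lru_cache(maxsize=None)
def _hamming(nbits: int) -> np.ndarray:
    """(2^nbits, 2^nbits) matrix of Hamming distances between cell indices."""
    m = 2**nbits
    a = np.arange(m)
    xor = a[:, None] ^ a[None, :]
    d = np.zeros_like(xor)
    while xor.any():
        d += xor & 1
        xor >>= 1
    return d.astype(np.float64)


def flip_kernel(p: float, nbits: int) -> np.ndarray:
    """Transition matrix T[c, a] = P(observed cell a | true cell c).

    Doubly stochastic for every p, so r sums to 1 whenever q does.
    """
    d = _hamming(nbits)
    # 0**0 == 1 handles p == 0 exactly
    return p**d * (1.0 - p) ** (nbits - d)


def em_fit(
    counts: CountTable | np.ndarray | Sequence[int],
    hyp: Hypothesis | int,
    init: tuple[np.ndarray, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
    polish: bool = False,
) -> EMResult:
    """Maximum-likelihood fit of ``(q, p)`` under one zero-cell hypothesis.

    Parameters
    ----------
    counts
        A :class:`~tdbn.counts.CountTable` or a flat vector of length
        ``2**(k+1)``.
    hyp
        The forbidden cell (index or :class:`Hypothesis`).
    init
        Optional ``(q0, p0)``.  The default start is the smoothed empirical
        distribution ``(counts + 1/2) / (N + M/2)`` with the forbidden
        cell's mass removed and p0 = 0.02 — strictly interior, so every
        observed cell has positive probability from the first E-step.
    tol
        Convergence threshold on the relative log-likelihood change.
    polish
        After the EM converges, re-maximise over a profile-likelihood grid
        in p (inner EM over q at each grid point) and keep the grid optimum
        if it improves the likelihood.  Near-flat tables put the likelihood
        on a ridge in p along which plain EM creeps arbitrarily slowly;
        the profile pass pins ``p_hat`` to the actual maximiser there.
    """
    n_obs = counts.counts if isinstance(counts, CountTable) else np.asarray(counts)
    n_obs = n_obs.astype(np.float64)
    M = n_obs.shape[0]
    nbits = int(np.log2(M))
    if 2**nbits != M:
        raise ValueError(f"counts length {M} is not a power of two")
    N = n_obs.sum()
    if N < 1:
        raise ValueError("p-score undefined for an empty table (N = 0)")
    forbidden = hyp.forbidden_cell if isinstance(hyp, Hypothesis) else int(hyp)
    if not 0 <= forbidden < M:
        raise ValueError(f"forbidden cell {forbidden} outside 0..{M - 1}")

    if n_obs[forbidden] == 0:
        # Hypothesis already satisfied by the data: q = empirical, p = 0 is
        # the global maximiser (it attains the unconstrained maximum).
        q = n_obs / N
        pos = n_obs > 0
        ll = float(np.sum(n_obs[pos] * np.log(q[pos])))
        return EMResult(0.0, q, ll, 0, True, np.array([ll]))

    d = _hamming(nbits)
    if init is None:
        q = (n_obs + 0.5) / (N + M / 2)
        q[forbidden] = 0.0
        q /= q.sum()
        p = 0.02
    else:
        q = np.asarray(init[0], dtype=np.float64).copy()
        q[forbidden] = 0.0
        q /= q.sum()
        p = float(init[1])

    obs = n_obs > 0
    ll_path = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T = p**d * (1.0 - p) ** (nbits - d)
        J = q[:, None] * T                     # joint P(true c, observed a)
        r = J.sum(axis=0)
        if np.any(r[obs] <= 0):
            raise FloatingPointError(
                "observed cell with zero probability under current "
                "parameters; supply an interior init"
            )
        ll = float(np.sum(n_obs[obs] * np.log(r[obs])))
        ll_path.append(ll)
        # E-step: expected splitting counts; M-step: reestimate q and p
        W = J * (n_obs / np.where(r > 0, r, 1.0))[None, :]
        q = W.sum(axis=1) / N
        q[forbidden] = 0.0
        s = q.sum()
        if s > 0:
            q /= s
        p = float(np.sum(d * W) / (nbits * N))
        p = min(max(p, 0.0), P_MAX)
        if ll - ll_prev <= tol * (abs(ll_prev) + 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
    # final log-likelihood at the returned parameters
    T = p**d * (1.0 - p) ** (nbits - d)
    r = (q[:, None] * T).sum(axis=0)
    ll = float(np.sum(n_obs[obs] * np.log(r[obs])))
    if polish:
        q_g, p_g, ll_g = _profile_grid_max(n_obs, forbidden, d, nbits)
        if ll_g > ll + 1e-12 * (abs(ll) + 1.0):
            q, p, ll = q_g, p_g, ll_g
            converged = True
    ll_path.append(ll)
    return EMResult(p, q, ll, it, converged, np.asarray(ll_path))


def _profile_grid_max(
    n_obs: np.ndarray,
    forbidden: int,
    d: np.ndarray,
    nbits: int,
    coarse: float = 0.01,
    fine: float = 5e-4,
    inner: int = 4000,
    tol: float = 1e-13,
) -> tuple[np.ndarray, float, float]:
    """Maximise the profile likelihood over a grid of flip probabilities.

    For every candidate p the inner EM over q alone solves a concave
    mixture-weight problem; the whole grid is iterated as one vectorised
    batch.  A coarse scan over [0, 0.5) is refined once around its argmax.
    """
    N = n_obs.sum()
    obs = n_obs > 0

    def scan(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        G = len(grid)
        T = grid[:, None, None] ** d[None] * (1 - grid[:, None, None]) ** (
            nbits - d[None]
        )
        M = n_obs.shape[0]
        q = np.tile((n_obs + 0.5) / (N + M / 2), (G, 1))
        q[:, forbidden] = 0.0
        q /= q.sum(axis=1, keepdims=True)
        ll = np.full(G, -np.inf)
        ll_prev = ll
        for _ in range(inner):
            J = q[:, :, None] * T
            r = J.sum(axis=1)
            r_safe = np.where(r > 0, r, 1.0)
            bad = (r[:, obs] <= 0).any(axis=1)
            ll = np.where(bad, -np.inf, (n_obs[obs] * np.log(r_safe[:, obs])).sum(axis=1))
            # a grid point is settled when its log-likelihood has stopped
            # moving; points stuck at -inf (infeasible p, e.g. p = 0 with a
            # positive forbidden count) are settled by definition
            stuck = np.isneginf(ll) & np.isneginf(ll_prev)
            with np.errstate(invalid="ignore"):
                gain = np.where(stuck, 0.0, ll - ll_prev)
            ref = np.abs(np.where(np.isfinite(ll_prev), ll_prev, 0.0)) + 1.0
            if np.all(stuck | (np.abs(gain) < tol * ref)):
                break
            ll_prev = ll
            W = J * (n_obs / r_safe)[:, None, :]
            q = W.sum(axis=2) / N
            q[:, forbidden] = 0.0
            s = q.sum(axis=1, keepdims=True)
            q = np.where(s > 0, q / np.where(s > 0, s, 1.0), q)
        return q, ll

    grid1 = np.arange(0.0, 0.5, coarse)
    q1, ll1 = scan(grid1)
    b1 = int(np.argmax(ll1))
    lo = max(0.0, grid1[b1] - coarse)
    hi = min(P_MAX, grid1[b1] + coarse)
    grid2 = np.clip(np.arange(lo, hi + fine / 2, fine), 0.0, P_MAX)
    q2, ll2 = scan(grid2)
    b2 = int(np.argmax(ll2))
    return q2[b2], float(grid2[b2]), float(ll2[b2])


def p_score_table(
    samples: Sequence[TransitionSample],
    target: int,
    inputs: Sequence[int],
    **em_kwargs,
) -> np.ndarray:
    """The ``2**(k+1)`` p-scores for one (input tuple, target) table,
    ordered by forbidden-cell index (q_000 ... q_111 for k = 2)."""
    tab = build_count_table(samples, target, inputs)
    return scores_for_counts(tab, **em_kwargs)


def scores_for_counts(tab: CountTable, **em_kwargs) -> np.ndarray:
    """p-scores for every zero-cell hypothesis of an existing count table."""
    m = 2 ** (tab.k + 1)
    return np.array(
        [em_fit(tab, Hypothesis(cell), **em_kwargs).p_hat for cell in range(m)]
    )
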