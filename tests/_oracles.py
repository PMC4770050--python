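"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's internal likelihood code: the grid
searches below evaluate probabilities directly from item parameters with
scipy primitives, so agreement with the package is a genuine cross-check
rather than the same code tested against itself.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

#: tiny floor so log() is defined even in impossible tails
_P_TINY = 1e-300


def grid_map_bifactor(y_mc, y_cr, pool, step=0.01, bound=4.0):
    """Exhaustive 3-D grid argmax of the bi-factor log posterior.

    The log posterior separates as A(theta_g, theta_mc) + B(theta_g, theta_cr)
    + prior(theta_g) because MC items involve only (theta_g, theta_mc) and CR
    items only (theta_g, theta_cr), so the exact joint argmax over the full
    cube is found from two 2-D grids per pattern.

    Returns an (n_patterns, 3) array of grid modes.
    """
    axis = np.round(np.arange(-bound, bound + step / 2.0, step), 10)
    y_mc = np.atleast_2d(np.asarray(y_mc, dtype=int))
    y_cr = np.atleast_2d(np.asarray(y_cr, dtype=int))
    prior = -0.5 * axis**2

    # MC block: shared log P(y=0) base plus a per-item delta added when y=1.
    mc_base = np.zeros((axis.size, axis.size))  # indexed [theta_g, theta_mc]
    mc_delta = []
    for it in pool.mc_items:
        z = it.a_g * axis[:, None] + it.a_mc * axis[None, :] - it.d
        p = np.clip(it.g + (1.0 - it.g) * ndtr(z), _P_TINY, 1.0 - 1e-16)
        lp0 = np.log1p(-p)
        mc_base += lp0
        mc_delta.append(np.log(p) - lp0)

    # CR block: per item the full (theta_g, theta_cr, category) log-prob grid.
    cr_logp = []
    for it in pool.cr_items:
        t = it.d + np.concatenate([[0.0], np.asarray(it.offsets)])
        z = it.a_g * axis[:, None] + it.a_cr * axis[None, :]
        ge = np.concatenate(
            [np.ones(z.shape + (1,)), ndtr(z[..., None] - t),
             np.zeros(z.shape + (1,))], axis=2,
        )
        cr_logp.append(np.log(np.clip(ge[..., :-1] - ge[..., 1:], _P_TINY, 1.0)))

    out = np.empty((y_mc.shape[0], 3))
    for i in range(y_mc.shape[0]):
        A = mc_base + prior[None, :]
        for delta, y in zip(mc_delta, y_mc[i]):
            if y == 1:
                A = A + delta
        B = np.tile(prior, (axis.size, 1))
        for logp, y in zip(cr_logp, y_cr[i]):
            B = B + logp[:, :, y]
        total = prior + A.max(axis=1) + B.max(axis=1)
        gi = int(total.argmax())
        out[i] = (axis[gi], axis[A[gi].argmax()], axis[B[gi].argmax()])
    return out


def grid_map_unidim(y_mc, y_cr, items, step=0.005, bound=4.0):
    """1-D grid argmax of the 3PL + logistic-GRM log posterior per pattern."""
    axis = np.round(np.arange(-bound, bound + step / 2.0, step), 10)
    y_mc = np.atleast_2d(np.asarray(y_mc, dtype=int))
    y_cr = np.atleast_2d(np.asarray(y_cr, dtype=int))
    out = np.empty(y_mc.shape[0])
    for i in range(y_mc.shape[0]):
        lp = -0.5 * axis**2
        for it, y in zip(items.mc_items, y_mc[i]):
            p = np.clip(it.g + (1.0 - it.g) * expit(it.a * (axis - it.b)),
                        _P_TINY, 1.0 - 1e-16)
            lp += np.log(p) if y == 1 else np.log1p(-p)
        for it, y in zip(items.cr_items, y_cr[i]):
            thr = np.asarray(it.thresholds)
            ge = np.concatenate(
                [np.ones((axis.size, 1)), expit(it.a * (axis[:, None] - thr)),
                 np.zeros((axis.size, 1))], axis=1,
            )
            lp += np.log(np.clip(ge[:, y] - ge[:, y + 1], _P_TINY, 1.0))
        out[i] = axis[lp.argmax()]
    return out


def largest_remainder_bruteforce(n, proportions):
    """Largest-remainder apportionment written the slow, obvious way."""
    quotas = [n * p for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n - sum(counts)
    # ties broken toward the lower category index
    order = sorted(range(len(proportions)), key=lambda k: (-remainders[k], k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def cronbach_alpha_reference(scores):
    """Coefficient alpha computed term by term from its textbook definition."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    sum_item_var = sum(np.var(scores[:, j], ddof=1) for j in range(k))
    total_var = np.var(scores.sum(axis=1), ddof=1)
    return k / (k - 1.0) * (1.0 - sum_item_var / total_var)
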