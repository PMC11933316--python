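"""Independent oracles used by the test suite.

The MLE oracle maximizes the same negative-binomial likelihood as the
package but by exhaustive search: an explicit grid on the selection
coefficient beta with per-guide baselines profiled out by derivative-free
ternary search (the log-likelihood is jointly concave in (log b, beta),
so the profile in beta is concave and a coarse-to-fine grid scan attains
the global optimum at the fine step).  The NB pmf comes from
scipy.stats.nbinom, not from the package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def nb_logpmf(k, mu, alpha):
    """NB log-pmf with Var = mu + alpha*mu^2 via scipy.stats.nbinom."""
    k = np.asarray(k, float)
    mu = np.asarray(mu, float)
    alpha = np.asarray(alpha, float)
    k, mu, alpha = np.broadcast_arrays(k, mu, alpha)
    out = np.empty(k.shape)
    small = alpha < 1e-12
    if small.any():
        out[small] = stats.poisson.logpmf(k[small], mu[small])
    big = ~small
    if big.any():
        n = 1.0 / alpha[big]
        p = n / (n + mu[big])
        out[big] = stats.nbinom.logpmf(k[big], n, p)
    return out


def _profile_loglik(betas, K, s, d, alpha, n_ternary=80):
    """Profiled log-likelihood at each beta of a single-contrast model.

    K: (I, R) counts; s: (R,) size factors; d: (R,) 0/1 contrast
    indicator; alpha: (I,) dispersions.  Baselines b_i are profiled by
    ternary search on log b (concave 1-D problems, independent per guide).
    """
    betas = np.asarray(betas, float)
    G, I, R = len(betas), K.shape[0], K.shape[1]
    mult = s[None, None, :] * np.exp(betas[:, None, None] * d[None, None, :])
    kk = np.broadcast_to(K[None], (G, I, R))
    aa = np.broadcast_to(alpha[None, :, None], (G, I, R))

    def ll_at(logb):  # logb: (G, I)
        mu = np.maximum(mult * np.exp(logb[:, :, None]), 1e-300)
        return nb_logpmf(kk, mu, aa).sum(axis=2)  # (G, I)

    lo = np.full((G, I), np.log(1e-4))
    hi = np.full((G, I), np.log(K.max() / s.min() + 10.0) + np.abs(betas).max() + 2.0)
    for _ in range(n_ternary):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        f1, f2 = ll_at(m1), ll_at(m2)
        take = f1 < f2
        lo = np.where(take, m1, lo)
        hi = np.where(take, hi, m2)
    return ll_at((lo + hi) / 2.0).sum(axis=1)  # (G,)


def grid_beta_mle(K, s, d, alpha, lo=-10.0, hi=10.0, step=1e-3):
    """Exhaustive-grid MLE of a single-contrast beta at resolution ``step``.

    Coarse scan of the full [lo, hi] range at 10x the step, then a fine
    scan at ``step`` around the coarse optimum (exact for the concave
    profile likelihood).
    """
    K = np.asarray(K, float)
    s = np.asarray(s, float)
    d = np.asarray(d, float)
    alpha = np.asarray(alpha, float)
    coarse = np.arange(lo, hi + 5e-3, 10 * step)
    b0 = coarse[np.argmax(_profile_loglik(coarse, K, s, d, alpha))]
    fine = np.arange(max(lo, b0 - 11 * step), min(hi, b0 + 11 * step) + step / 2, step)
    return float(fine[np.argmax(_profile_loglik(fine, K, s, d, alpha))])
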