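"""Two-state hidden-state segmentation of methylation signals.

The model family follows the standard WGBS segmentation approach: a two-state
Markov chain along the genome, with state 0 the low-methylation state (HMR, or
the partially-methylated state for domain calling) and state 1 the
high/background state.  Emissions are

* beta-binomial on per-CpG methylated-read counts (HMR calling), with the
  state mean fitted and a fixed concentration ``conc`` (larger = closer to
  binomial), or
* Gaussian on binned mean levels (PMD calling), with state means and
  variances fitted.

Parameters are fitted by expectation-maximization with a deterministic
initialization from the level histogram (low state seeded from observations
below 0.5, high state from the rest), so segmentation involves no randomness.
Decoding is posterior (state 0 wherever its posterior probability exceeds
0.5).  Chromosomes are pre-split into fragments at large CpG gaps by the
callers; fragments share parameters but are decoded independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

__all__ = ["TwoStateFit", "segment_betabinom", "segment_gaussian"]

_EPS = 1e-300


@dataclass
class TwoStateFit:
    """Fitted parameters of the two-state chain."""

    mean_low: float
    mean_high: float
    trans: np.ndarray  # 2x2 row-stochastic
    n_iter: int
    log_likelihood: float


def _forward_backward(lik: np.ndarray, trans: np.ndarray, start: np.ndarray):
    """Scaled forward-backward on one fragment.

    lik: (T, 2) emission likelihoods (linear scale, may be tiny but > 0).
    Returns (gamma, xi_sum, loglik): posterior state probs, summed two-slice
    posteriors (2, 2), and the fragment log-likelihood.
    """
    T = lik.shape[0]
    alpha = np.empty((T, 2))
    scale = np.empty(T)
    a = start * lik[0]
    scale[0] = a.sum() + _EPS
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * lik[t]
        scale[t] = a.sum() + _EPS
        alpha[t] = a / scale[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        b = trans * (lik[t + 1] * beta[t + 1])[None, :]
        xi = alpha[t][:, None] * b
        s = xi.sum() + _EPS
        xi_sum += xi / s
        beta[t] = b.sum(axis=1) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True) + _EPS
    return gamma, xi_sum, float(np.log(scale).sum())


def _betabinom_loglik(k: np.ndarray, n: np.ndarray, mu: float, conc: float):
    a = max(mu, 1e-4) * conc
    b = max(1.0 - mu, 1e-4) * conc
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


def _norm_loglik(x: np.ndarray, mu: float, var: float):
    var = max(var, 1e-6)
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _em(
    fragments: list,
    loglik_fn,
    mstep_fn,
    params: dict,
    trans: np.ndarray,
    max_iter: int,
    tol: float,
):
    start = np.array([0.5, 0.5])
    prev_ll = -np.inf
    n_iter = 0
    gammas: list[np.ndarray] = []
    total_ll = 0.0
    for n_iter in range(1, max_iter + 1):
        gammas = []
        xi_total = np.zeros((2, 2))
        total_ll = 0.0
        for obs in fragments:
            ll = np.stack(
                [loglik_fn(obs, params, 0), loglik_fn(obs, params, 1)], axis=1
            )
            ll -= ll.max(axis=1, keepdims=True)
            gamma, xi, frag_ll = _forward_backward(np.exp(ll), trans, start)
            gammas.append(gamma)
            xi_total += xi
            total_ll += frag_ll
        params = mstep_fn(fragments, gammas, params)
        denom = xi_total.sum(axis=1, keepdims=True)
        if (denom > 0).all():
            trans = (xi_total + 1e-6) / (denom + 2e-6)
        if abs(total_ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            break
        prev_ll = total_ll
    return gammas, params, trans, n_iter, total_ll


def segment_betabinom(
    fragments: list[tuple[np.ndarray, np.ndarray]],
    init_means: tuple[float, float],
    conc: float = 15.0,
    stay_prob: float = 0.99,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> tuple[list[np.ndarray], TwoStateFit]:
    """Fit + decode on per-CpG counts.

    fragments: list of ``(meth_reads, total_reads)`` arrays (one per
    gap-delimited fragment).  Returns per-fragment posterior probability of
    the low state, and the fit.
    """

    def loglik(obs, params, state):
        k, n = obs
        return _betabinom_loglik(k, n, params["mu"][state], conc)

    def mstep(frs, gammas, params):
        num = np.zeros(2)
        den = np.zeros(2)
        for (k, n), g in zip(frs, gammas):
            num += (g * k[:, None]).sum(axis=0)
            den += (g * n[:, None]).sum(axis=0)
        mu = np.where(den > 0, num / np.maximum(den, 1e-12), params["mu"])
        # keep the state identity fixed: state 0 stays the lower-mean state
        mu = np.sort(np.clip(mu, 1e-4, 1 - 1e-4))
        return {"mu": mu}

    params = {"mu": np.sort(np.clip(np.asarray(init_means, float), 1e-4, 1 - 1e-4))}
    trans = np.array([[stay_prob, 1 - stay_prob], [1 - stay_prob, stay_prob]])
    gammas, params, trans, n_iter, ll = _em(
        fragments, loglik, mstep, params, trans, max_iter, tol
    )
    fit = TwoStateFit(float(params["mu"][0]), float(params["mu"][1]), trans, n_iter, ll)
    return [g[:, 0] for g in gammas], fit


def segment_gaussian(
    fragments: list[np.ndarray],
    init_means: tuple[float, float],
    init_sd: float = 0.1,
    stay_prob: float = 0.995,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> tuple[list[np.ndarray], TwoStateFit]:
    """Fit + decode on binned mean levels (one value per assessable bin)."""

    def loglik(obs, params, state):
        return _norm_loglik(obs, params["mu"][state], params["var"][state])

    def mstep(frs, gammas, params):
        w = np.zeros(2)
        s1 = np.zeros(2)
        s2 = np.zeros(2)
        for x, g in zip(frs, gammas):
            w += g.sum(axis=0)
            s1 += (g * x[:, None]).sum(axis=0)
            s2 += (g * (x**2)[:, None]).sum(axis=0)
        mu = np.where(w > 0, s1 / np.maximum(w, 1e-12), params["mu"])
        var = np.where(
            w > 1, s2 / np.maximum(w, 1e-12) - mu**2, params["var"]
        )
        order = np.argsort(mu)
        return {"mu": mu[order], "var": np.maximum(var[order], 1e-5)}

    params = {
        "mu": np.sort(np.asarray(init_means, float)),
        "var": np.array([init_sd**2, init_sd**2]),
    }
    trans = np.array([[stay_prob, 1 - stay_prob], [1 - stay_prob, stay_prob]])
    gammas, params, trans, n_iter, ll = _em(
        fragments, loglik, mstep, params, trans, max_iter, tol
    )
    fit = TwoStateFit(float(params["mu"][0]), float(params["mu"][1]), trans, n_iter, ll)
    return [g[:, 0] for g in gammas], fit
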