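"""Independent reference computations used to check the implementation.

Everything here is deliberately written from first principles (enumeration,
closed forms, quadrature) and does not reuse the filtering code paths it is
meant to validate.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def two_state_transition(k12: float, k21: float, dt: float) -> np.ndarray:
    """Closed-form propagator of a two-state chain (column-stochastic)."""
    s = k12 + k21
    if s == 0:
        return np.eye(2)
    e = np.exp(-s * dt)
    p1_inf = k21 / s  # stationary prob of state 1
    # column j: start in state j
    T = np.empty((2, 2))
    T[0, 0] = p1_inf + (1 - p1_inf) * e
    T[1, 0] = 1 - T[0, 0]
    T[0, 1] = p1_inf - p1_inf * e
    T[1, 1] = 1 - T[0, 1]
    return T


def exact_forward_loglik_2state(
    y: np.ndarray,
    Nch: int,
    T_stack: np.ndarray,
    seg_idx: np.ndarray,
    p0_open: float,
    i_curr: float,
    sigma_m: float,
    sigma_op: float,
) -> float:
    """Exact HMM forward-algorithm log-likelihood over count states.

    For a 2-state channel the ensemble state is fully described by the
    number of open channels n in 0..Nch.  The one-step transition of n is
    the sum of two independent binomials (channels staying open and closed
    channels opening); its pmf is computed by convolution.  Emissions are
    ``N(i*n, sigma_m^2 + sigma_op^2*n)``.  The first sample is weighted by
    the initial (equilibrium binomial) distribution without propagation.
    """
    ns = np.arange(Nch + 1)

    def step_matrix(T):
        p_stay_open = T[1, 1]  # open -> open
        p_open = T[1, 0]  # closed -> open
        A = np.zeros((Nch + 1, Nch + 1))
        for n in ns:
            a = stats.binom.pmf(np.arange(n + 1), n, p_stay_open)
            b = stats.binom.pmf(np.arange(Nch - n + 1), Nch - n, p_open)
            A[: Nch + 1, n] = np.convolve(a, b)[: Nch + 1]
        return A  # column-stochastic over n' given n

    mats = [step_matrix(T) for T in T_stack]
    alpha = stats.binom.pmf(ns, Nch, p0_open)
    ll = 0.0
    for t in range(len(y)):
        if t > 0:
            alpha = mats[seg_idx[t]] @ alpha
        w = stats.norm.pdf(y[t], i_curr * ns, np.sqrt(sigma_m**2 + sigma_op**2 * ns))
        alpha = alpha * w
        norm = alpha.sum()
        if norm <= 0:
            return -np.inf
        ll += np.log(norm)
        alpha = alpha / norm
    return float(ll)


def state_dependent_marginal_moments(
    nbar: float, P: float, sigma_m: float, sigma_op: float, n_sigma: float = 12.0
):
    """Quadrature moments of ``int N(y|n, sigma_m^2 + n sigma_op^2) N(n|nbar,P) dn``.

    Scalar toy for the state-dependent-noise marginal; the noise variance is
    clipped at sigma_m^2 for (improbable) negative n.
    """
    sd = np.sqrt(P)
    lo, hi = nbar - n_sigma * sd, nbar + n_sigma * sd

    def var_of(n):
        return sigma_m**2 + sigma_op**2 * max(n, 0.0)

    def moment(k):
        def integrand(y, n):
            return (
                y**k
                * stats.norm.pdf(y, n, np.sqrt(var_of(n)))
                * stats.norm.pdf(n, nbar, sd)
            )

        val, _ = integrate.dblquad(
            integrand,
            lo,
            hi,
            lambda n: n - n_sigma * np.sqrt(var_of(n)),
            lambda n: n + n_sigma * np.sqrt(var_of(n)),
            epsabs=1e-10,
        )
        return val

    m1 = moment(1)
    m2 = moment(2)
    return m1, m2 - m1**2


def multinomial_cov(n: int, p: np.ndarray) -> np.ndarray:
    return n * (np.diag(p) - np.outer(p, p))
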