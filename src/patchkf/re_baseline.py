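"""Rate-equation (RE) baseline likelihood.

The classical deterministic approach propagates only the mean occupancy,
``nbar(t+1) = T nbar(t)``, with no data-driven correction step, and treats
every data point as an independent draw from a multinomial distribution
centred on the deterministic mean:

    C(t) = diag(nbar) - nbar nbar^T / Nch          (multinomial covariance)
    y(t) ~ N(H nbar, H C H^T + Sigma(nbar))        (independent per point)

It shares H and the state-dependent noise law Sigma with the Kalman filter,
so the two likelihoods coincide on a single-point trace.  Because the RE
model ignores that the ensemble carries its state across samples, its
residuals on finite-Nch data retain the autocorrelation of the intrinsic
gating/binding fluctuations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .kalman import LOG2PI, FilterResult, ObservationModel, _trace_inputs, init_state
from .schemes import KineticScheme
from .simulate import NoiseParams, TraceSet

__all__ = ["re_mean_trajectory", "re_filter_trace", "re_loglik_traceset"]


def re_mean_trajectory(
    scheme: KineticScheme,
    rates: dict[str, float],
    Nch: float,
    times: np.ndarray,
    L: float,
    t_on: float,
    f_ana: float,
) -> np.ndarray:
    """Deterministic mean occupancy (N, M) on the analysis grid.

    Pure forward model: no data dependence.  Equals ``expm(K t) nbar0``
    piecewise over the protocol segments.
    """
    T_stack, seg_idx, K0 = _trace_inputs(scheme, rates, L, f_ana, times, t_on)
    n = init_state(K0, Nch).nbar
    out = np.empty((len(times), n.shape[0]))
    out[0] = n
    for t in range(1, len(times)):
        n = T_stack[seg_idx[t]] @ n
        out[t] = n
    return out


@njit(cache=True)
def _re_core(nbar0, T_stack, seg_idx, H, base_var, var_slope, var_floor, y, Nch):
    N, K = y.shape
    n = nbar0.copy()
    resid = np.empty((N, K))
    ll = 0.0
    for t in range(N):
        if t > 0:
            n = T_stack[seg_idx[t]] @ n
        npos = np.maximum(n, 0.0)
        C = np.diag(npos) - np.outer(n, n) / Nch
        sig = np.maximum(base_var + var_slope @ npos, var_floor)
        S = H @ (C @ H.T)
        for k in range(K):
            S[k, k] += sig[k]
        S = 0.5 * (S + S.T)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            tr = np.trace(S)
            jit = 1e-10 * max(tr, 1e-30)
            for _ in range(5):
                for k in range(K):
                    S[k, k] += jit
                sign, logdet = np.linalg.slogdet(S)
                if sign > 0:
                    break
                jit *= 100.0
            if sign <= 0:
                return -np.inf, resid
        r = y[t] - H @ n
        x = np.linalg.solve(S, r)
        ll += -0.5 * (K * LOG2PI + logdet + r @ x)
        for k in range(K):
            resid[t, k] = r[k] / np.sqrt(S[k, k])
    return ll, resid


def re_filter_trace(
    scheme: KineticScheme,
    rates: dict[str, float],
    noise: NoiseParams,
    Nch: float,
    y: np.ndarray,
    times: np.ndarray,
    L: float,
    t_on: float,
    f_ana: float,
    observables: tuple[str, ...] = ("fluorescence", "current"),
    collect_residuals: bool = False,
):
    """RE log-likelihood (and residuals) for one concentration trace."""
    obs = ObservationModel.from_scheme(scheme, noise, observables)
    T_stack, seg_idx, K0 = _trace_inputs(scheme, rates, L, f_ana, times, t_on)
    nbar0 = init_state(K0, Nch).nbar
    ll, resid = _re_core(
        nbar0,
        T_stack,
        seg_idx,
        obs.H,
        obs.base_var,
        obs.var_slope,
        obs.var_floor,
        np.ascontiguousarray(y, dtype=np.float64),
        float(Nch),
    )
    return ll, (resid if collect_residuals else None)


def re_loglik_traceset(
    scheme: KineticScheme,
    rates: dict[str, float],
    noise: NoiseParams,
    Nch: float,
    traces: TraceSet,
    collect_residuals: bool = False,
) -> FilterResult:
    """Total RE log-likelihood of a trace set (points treated independently)."""
    observables = ("fluorescence", "current") if traces.fluorescence is not None else (
        "current",
    )
    per_trace = np.empty(traces.n_traces)
    residuals = [] if collect_residuals else None
    n_pts = 0
    for c, L in enumerate(traces.concentrations):
        y = traces.y(c)
        ll, resid = re_filter_trace(
            scheme,
            rates,
            noise,
            Nch,
            y,
            traces.times,
            L,
            traces.t_on,
            traces.f_ana,
            observables,
            collect_residuals,
        )
        per_trace[c] = ll
        n_pts += y.shape[0]
        if collect_residuals:
            residuals.append(resid)
    return FilterResult(
        loglik=float(per_trace.sum()),
        per_trace=per_trace,
        residuals=residuals,
        n_points=n_pts,
    )
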