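"""Generalized Kalman filter with state-dependent observation noise.

The hidden state of the filter is the ensemble occupancy count vector n(t)
of Nch independent channels, summarized by its mean ``nbar`` and covariance
``P``.  Prediction propagates both moments exactly for the generalized
multinomial one-step transition distribution:

    nbar'  = T nbar
    P'     = Q(T, nbar) + T P T^T,
    Q      = diag(T nbar) - T diag(nbar) T^T,

and correction is the conjugate-normal Bayesian update with the
minimum-variance gain ``G = P H^T S^-1``, ``S = H P H^T + Sigma``.  The
observation noise Sigma is state dependent (open-channel excess noise and
Poisson photon counting) and is evaluated at the prior mean via the law of
total variance, which keeps the per-point marginal likelihood a normal
density matched to the exact first two moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .schemes import (
    KineticScheme,
    RateMatrix,
    TransitionMatrix,
    build_rate_matrix,
    equilibrium_distribution,
    transition_matrix,
)
from .simulate import NoiseParams, TraceSet

__all__ = [
    "EnsembleState",
    "ObservationModel",
    "Innovation",
    "FilterResult",
    "init_state",
    "predict",
    "process_noise",
    "observation_covariance",
    "innovation",
    "correct",
    "filter_trace",
    "loglik_traceset",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EnsembleState:
    """Mean occupancy ``nbar`` (channels) and covariance ``P`` (channels^2)."""

    nbar: np.ndarray
    P: np.ndarray


@dataclass
class ObservationModel:
    """Linear observation map plus diagonal state-dependent noise law.

    ``y = H n + noise`` with per-observable variance
    ``Sigma_kk(nbar) = max(base_var[k] + var_slope[k, :] @ max(nbar, 0),
    var_floor[k])``.

    For the current row: H = i * conducting, base = sigma_m^2, slope =
    sigma_op^2 * conducting, floor 0.  For the fluorescence row: H =
    lambda_b * bound_ligands, base = sigma_back^2, slope = H (Poisson
    variance equals the mean), floor 1/12.  The 1/12 floor is a continuity
    correction: photon counts are integers, so the normal approximation to
    their distribution is never narrower than a unit histogram bin; without
    it the predicted density at zero counts diverges as the Poisson rate
    goes to zero (e.g. after washout), which would reward arbitrarily fast
    rates.  Occupancy-dependent variance terms are clipped at zero even if
    the posterior mean dips slightly negative.
    """

    #: continuity-correction variance of a unit-width integer bin
    COUNT_FLOOR_VAR = 1.0 / 12.0

    H: np.ndarray
    base_var: np.ndarray
    var_slope: np.ndarray
    var_floor: np.ndarray
    labels: tuple[str, ...]

    @classmethod
    def from_scheme(
        cls,
        scheme: KineticScheme,
        noise: NoiseParams,
        observables: tuple[str, ...] = ("fluorescence", "current"),
    ) -> "ObservationModel":
        rows, base, slope, floor = [], [], [], []
        for obs in observables:
            if obs == "current":
                h = noise.i * scheme.conducting_vector()
                rows.append(h)
                base.append(noise.sigma_m**2)
                slope.append(noise.sigma_op**2 * scheme.conducting_vector())
                floor.append(0.0)
            elif obs == "fluorescence":
                h = noise.lambda_b * scheme.bound_vector()
                rows.append(h)
                base.append(noise.sigma_back**2)
                slope.append(h.copy())
                floor.append(cls.COUNT_FLOOR_VAR)
            else:
                raise ValueError(f"unknown observable {obs!r}")
        return cls(
            H=np.vstack(rows),
            base_var=np.array(base),
            var_slope=np.vstack(slope),
            var_floor=np.array(floor),
            labels=tuple(observables),
        )

    @property
    def n_obs(self) -> int:
        return self.H.shape[0]


@dataclass
class Innovation:
    """One-step-ahead residual, its covariance S and the log-likelihood."""

    residual: np.ndarray
    S: np.ndarray
    loglik: float


@dataclass
class FilterResult:
    """Filter output over a whole trace set."""

    loglik: float
    per_trace: np.ndarray
    residuals: list[np.ndarray] | None = None  # normalized, one (N, n_obs) per trace
    n_points: int = 0


def init_state(K: RateMatrix | np.ndarray, Nch: int | float) -> EnsembleState:
    """Equilibrium initialization: multinomial mean and covariance.

    ``nbar = Nch p_eq`` and ``P = Nch (diag(p_eq) - p_eq p_eq^T)``.
    """
    p = equilibrium_distribution(K)
    return EnsembleState(nbar=Nch * p, P=Nch * (np.diag(p) - np.outer(p, p)))


def process_noise(T: np.ndarray, nbar: np.ndarray) -> np.ndarray:
    """Generalized-multinomial process noise Q(T, nbar).

    Q is PSD for any column-stochastic T and nbar >= 0; the mean occupancy
    is clipped at zero here because the moment expansion is only meaningful
    for nonnegative counts (the posterior mean may dip slightly below zero
    at low occupancy and is deliberately not clamped elsewhere).
    """
    npos = np.clip(nbar, 0.0, None)
    return np.diag(T @ npos) - T @ np.diag(npos) @ T.T


def predict(state: EnsembleState, T: TransitionMatrix | np.ndarray) -> EnsembleState:
    """Propagate the moments one analysis step (symmetrized covariance)."""
    Tm = T.T if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    nbar = Tm @ state.nbar
    P = process_noise(Tm, state.nbar) + Tm @ state.P @ Tm.T
    return EnsembleState(nbar=nbar, P=0.5 * (P + P.T))


def observation_covariance(state: EnsembleState, obs: ObservationModel) -> np.ndarray:
    """Diagonal observation-noise covariance evaluated at the prior mean."""
    sig = obs.base_var + obs.var_slope @ np.clip(state.nbar, 0.0, None)
    return np.diag(np.maximum(sig, obs.var_floor))


def innovation(state: EnsembleState, obs: ObservationModel, y: np.ndarray) -> Innovation:
    """Residual, innovation covariance S = H P H^T + Sigma and log N(y|.., S)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observation")
    S = obs.H @ state.P @ obs.H.T + observation_covariance(state, obs)
    S = 0.5 * (S + S.T)
    jitter = 1e-10 * max(np.trace(S), 1e-300)
    while True:
        try:
            chol = np.linalg.cholesky(S)
            break
        except np.linalg.LinAlgError:
            S = S + jitter * np.eye(S.shape[0])
            jitter *= 100.0
            if jitter > 1e-4 * max(np.trace(S), 1e-300):
                raise
    r = y - obs.H @ state.nbar
    z = np.linalg.solve(chol, r)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    ll = -0.5 * (len(y) * LOG2PI + logdet + z @ z)
    return Innovation(residual=r, S=S, loglik=float(ll))


def correct(state: EnsembleState, obs: ObservationModel, y: np.ndarray) -> EnsembleState:
    """Bayesian measurement update with gain ``G = P H^T S^-1``."""
    inn = innovation(state, obs, y)
    G = state.P @ obs.H.T @ np.linalg.inv(inn.S)
    nbar = state.nbar + G @ inn.residual
    # Joseph form: PSD-preserving covariance update
    ImGH = np.eye(len(nbar)) - G @ obs.H
    P = ImGH @ state.P @ ImGH.T + G @ observation_covariance(state, obs) @ G.T
    P = 0.5 * (P + P.T)
    # PSD projection for pathological round-off only
    w, V = np.linalg.eigh(P)
    floor = -1e-8 * max(np.trace(P), 1.0)
    if np.any(w < floor):
        P = (V * np.clip(w, 0.0, None)) @ V.T
    return EnsembleState(nbar=nbar, P=P)


# ---------------------------------------------------------------------------
# fast whole-trace filtering (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _kf_core(nbar0, P0, T_stack, seg_idx, H, base_var, var_slope, var_floor, y, corrected):
    """Predict/correct along one trace; returns (loglik, normalized residuals).

    The first sample is evaluated against the equilibrium prior without
    propagation; with ``corrected=False`` the correction step is skipped
    (rate-equation-style filtering is handled by a separate core).
    """
    N, K = y.shape
    M = nbar0.shape[0]
    n = nbar0.copy()
    P = P0.copy()
    resid = np.empty((N, K))
    ll = 0.0
    for t in range(N):
        if t > 0:
            T = T_stack[seg_idx[t]]
            n_prev = np.maximum(n, 0.0)  # Q is PSD only at nonneg occupancy
            n = T @ n
            Q = np.diag(T @ n_prev) - T @ (np.diag(n_prev) @ T.T)
            P = Q + T @ (P @ T.T)
            P = 0.5 * (P + P.T)
        npos = np.maximum(n, 0.0)
        sig = np.maximum(base_var + var_slope @ npos, var_floor)
        S = H @ (P @ H.T)
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
        if corrected:
            G = np.linalg.solve(S, H @ P).T  # = P H^T S^-1 (P symmetric)
            n = n + G @ r
            ImGH = np.eye(M) - G @ H  # Joseph form keeps P PSD
            P = ImGH @ (P @ ImGH.T)
            for k in range(K):
                P += sig[k] * np.outer(G[:, k], G[:, k])
            P = 0.5 * (P + P.T)
    return ll, resid


def _segment_index(times: np.ndarray, t_on: float) -> np.ndarray:
    return (times > t_on + 1e-9).astype(np.int64)


def _trace_inputs(
    scheme: KineticScheme,
    rates: dict[str, float],
    L: float,
    f_ana: float,
    times: np.ndarray,
    t_on: float,
    L_init: float = 0.0,
):
    """Transition-matrix stack, segment index and initial state for one trace."""
    dt = 1.0 / f_ana
    T_on = transition_matrix(build_rate_matrix(scheme, rates, L), dt).T
    T_off = transition_matrix(build_rate_matrix(scheme, rates, 0.0), dt).T
    T_stack = np.stack([T_on, T_off])
    seg_idx = _segment_index(times, t_on)
    K0 = build_rate_matrix(scheme, rates, L_init)
    return T_stack, seg_idx, K0


def filter_trace(
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
    """Run the generalized Kalman filter over one concentration trace.

    Returns ``(loglik, normalized_residuals or None)``.
    """
    obs = ObservationModel.from_scheme(scheme, noise, observables)
    T_stack, seg_idx, K0 = _trace_inputs(scheme, rates, L, f_ana, times, t_on)
    state0 = init_state(K0, Nch)
    ll, resid = _kf_core(
        state0.nbar,
        state0.P,
        T_stack,
        seg_idx,
        obs.H,
        obs.base_var,
        obs.var_slope,
        obs.var_floor,
        np.ascontiguousarray(y, dtype=np.float64),
        True,
    )
    return ll, (resid if collect_residuals else None)


def loglik_traceset(
    scheme: KineticScheme,
    rates: dict[str, float],
    noise: NoiseParams,
    Nch: float,
    traces: TraceSet,
    collect_residuals: bool = False,
) -> FilterResult:
    """Total KF log-likelihood of a trace set (sum over concentrations).

    Deterministic for fixed inputs; numerical failures carry the trace index.
    """
    observables = ("fluorescence", "current") if traces.fluorescence is not None else (
        "current",
    )
    per_trace = np.empty(traces.n_traces)
    residuals = [] if collect_residuals else None
    n_pts = 0
    for c, L in enumerate(traces.concentrations):
        y = traces.y(c)
        try:
            ll, resid = filter_trace(
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
        except Exception as err:  # noqa: BLE001 - annotate trace context
            raise RuntimeError(f"filter failed on trace {c} (L={L} uM): {err}") from err
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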