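"""Evaluation machinery: residual whiteness, credible volumes, coverage.

The diagnostics answer two questions about an inference algorithm:

* does it model the data-generating process correctly?  If so, the
  one-step-ahead normalized residuals ``r(t) = (y - H nbar_pred) / sd_pred``
  are white noise with unit variance;
* is its posterior an honest representation of uncertainty?  Across repeated
  synthetic data sets, the probability mass one must accumulate around the
  posterior mode before covering the true parameters behaves like a draw
  from the nominal coverage law (binomial calibration of HDCVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ResidualSeries",
    "CoverageResult",
    "normalized_residuals",
    "autocorrelation",
    "whiteness_band",
    "euclidean_error",
    "hdci",
    "mass_to_cover_histogram",
    "mass_to_cover_mahalanobis",
    "coverage_calibration",
    "joint_coverage_bounds",
    "fit_error_scaling",
    "improper_posterior_flag",
]


@dataclass
class ResidualSeries:
    """Normalized one-step-ahead residuals per observable."""

    residuals: np.ndarray  # (N, n_obs), traces concatenated
    labels: tuple[str, ...]

    def variance(self) -> float:
        """Pooled sample variance over all points and observables."""
        return float(np.var(self.residuals))


@dataclass
class CoverageResult:
    """Beta posterior over a true success rate from binomial trials."""

    successes: int
    trials: int
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def interval(self, mass: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - mass) / 2.0
        d = stats.beta(self.alpha, self.beta)
        return float(d.ppf(lo)), float(d.ppf(1.0 - lo))


def normalized_residuals(traces, rates, noise, Nch, scheme, method: str = "kf") -> ResidualSeries:
    """Run the KF or RE over a trace set and pool the normalized residuals.

    Residuals are one-step-ahead: the prediction for sample t uses data up to
    t-1 (KF) or no data at all (RE), divided by the predicted standard
    deviation of that observable.
    """
    if method == "kf":
        from .kalman import loglik_traceset as run
    elif method == "re":
        from .re_baseline import re_loglik_traceset as run
    else:
        raise ValueError("method must be 'kf' or 're'")
    res = run(scheme, rates, noise, Nch, traces, collect_residuals=True)
    pooled = np.vstack(res.residuals)
    if not np.all(np.isfinite(pooled)):
        raise ValueError("residuals undefined: zero predicted variance somewhere")
    labels = ("fluorescence", "current") if traces.fluorescence is not None else ("current",)
    return ResidualSeries(residuals=pooled, labels=labels)


def autocorrelation(r: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 1..max_lag of a 1-D series."""
    r = np.asarray(r, dtype=float)
    N = r.shape[0]
    if N <= max_lag:
        raise ValueError("series shorter than max_lag")
    r = r - r.mean()
    denom = float(r @ r)
    if denom == 0.0:
        raise ValueError("constant series: autocorrelation undefined")
    return np.array([float(r[: N - k] @ r[k:]) / denom for k in range(1, max_lag + 1)])


def whiteness_band(n: int, n_lags: int, familywise: float = 0.05) -> float:
    """Simultaneous white-noise band half-width for ``n_lags`` ACF estimates.

    Under the white-noise null each lag estimate is ~N(0, 1/n); a Bonferroni
    correction keeps the familywise false-alarm rate at ``familywise``.
    """
    z = stats.norm.ppf(1.0 - familywise / (2.0 * n_lags))
    return float(z / np.sqrt(n))


def euclidean_error(theta: np.ndarray, theta_true: np.ndarray) -> float:
    """Accuracy summary ``sum_i (theta_i / theta_true_i - 1)^2``.

    Computed over the rate-matrix parameters (rates and equilibrium
    constants); as printed, a sum of squares without the square root.
    """
    theta = np.asarray(theta, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta.shape != theta_true.shape:
        raise ValueError("shape mismatch")
    if np.any(theta_true == 0):
        raise ValueError("theta_true entries must be nonzero")
    return float(np.sum((theta / theta_true - 1.0) ** 2))


def hdci(samples: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the empirical distribution."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def mass_to_cover_histogram(
    samples: np.ndarray, theta_true: np.ndarray, bins: int | None = None
) -> tuple[float, bool]:
    """Probability mass of highest-density histogram bins up to the true value.

    Bins of an n-D histogram of the draws are ranked by count; mass is
    accumulated from the highest bin down until the bin containing
    ``theta_true`` is absorbed.  Returns ``(mass, in_support)``; if the true
    value lies outside the sampled hyper-rectangle or in an empty bin, mass
    1.0 is returned with ``in_support=False``.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty samples")
    S, dim = X.shape
    if bins is None:
        bins = max(2, int(np.ceil(S ** (1.0 / (dim + 2)))))
    H, edges = np.histogramdd(X, bins=bins)
    theta_true = np.atleast_1d(np.asarray(theta_true, dtype=float))
    idx = []
    for d in range(dim):
        e = edges[d]
        if theta_true[d] < e[0] or theta_true[d] > e[-1]:
            return 1.0, False
        j = int(np.searchsorted(e, theta_true[d], side="right")) - 1
        idx.append(min(j, H.shape[d] - 1))
    true_count = H[tuple(idx)]
    if true_count == 0:
        return 1.0, False
    flat = np.sort(H.ravel())[::-1]
    # accumulate strictly-higher bins, then all bins tied with the true bin
    mass = flat[flat > true_count].sum() + true_count * np.count_nonzero(
        flat == true_count
    )
    return float(mass / S), True


def mass_to_cover_mahalanobis(samples: np.ndarray, theta_true: np.ndarray) -> float:
    """Chi-square mass inside the Mahalanobis ellipsoid through the true value.

    Under a multivariate-normal posterior the mass within distance d of the
    mean is ``chi2.cdf(d^2, dim)``; this is the analytic counterpart of the
    histogram method.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    mu = X.mean(axis=0)
    C = np.cov(X, rowvar=False).reshape(X.shape[1], X.shape[1])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular sample covariance") from err
    d = np.atleast_1d(np.asarray(theta_true, dtype=float)) - mu
    d2 = float(d @ Cinv @ d)
    return float(stats.chi2.cdf(d2, df=X.shape[1]))


def coverage_calibration(successes: int, trials: int) -> CoverageResult:
    """Beta(1+s, 1+n-s) posterior over the true coverage probability.

    Conjugate update of a uniform Beta(1,1) prior with a binomial likelihood
    for 'the HDCV covered the true parameters' events.
    """
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    return CoverageResult(
        successes=successes,
        trials=trials,
        alpha=1.0 + successes,
        beta=1.0 + trials - successes,
    )


def joint_coverage_bounds(mass: float = 0.95, n_params: int = 6) -> tuple[float, float]:
    """Bounds for the joint success rate of ``n_params`` marginal HDCIs.

    Lower bound: independence, ``mass**n_params`` (e.g. 0.95^6 ~ 0.735);
    upper bound: perfect dependence, ``mass``.
    """
    return mass**n_params, mass


def fit_error_scaling(errors: np.ndarray, Nch_values: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``error(Nch) = a / sqrt(Nch)`` on the log scale.

    Returns ``(a, residual_sd)`` where ``residual_sd`` is the RMS log-scale
    misfit (large values flag that the 1/sqrt(Nch) law does not hold).  The
    ratio of two fitted ``a`` values is the benchmark error ratio.
    """
    errors = np.asarray(errors, dtype=float)
    Nch_values = np.asarray(Nch_values, dtype=float)
    if len(errors) < 3:
        raise ValueError("need at least 3 points")
    if np.any(errors <= 0) or np.any(Nch_values <= 0):
        raise ValueError("errors and Nch must be positive")
    log_a = np.log(errors) + 0.5 * np.log(Nch_values)
    a = float(np.exp(log_a.mean()))
    resid_sd = float(np.sqrt(np.mean((log_a - log_a.mean()) ** 2)))
    return a, resid_sd


def improper_posterior_flag(
    samples: np.ndarray, lo: np.ndarray, hi: np.ndarray, frac: float = 0.01
) -> bool:
    """Sample-based improper-posterior detection.

    Flags the posterior as (numerically) improper when at least ``frac`` of
    the draws of any parameter pile within 0.1% of a sampling-box bound,
    i.e. the posterior is confined only by the box.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    width = hi - lo
    near = (X < lo + 1e-3 * width) | (X > hi - 1e-3 * width)
    return bool(np.any(near.mean(axis=0) >= frac))
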