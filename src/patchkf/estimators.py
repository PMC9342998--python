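"""Scikit-learn-style estimator over the Bayesian filter.

``KineticModelEstimator`` wraps posterior sampling in a fit/score interface
(hmmlearn-style): ``fit(traces)`` samples the posterior of the free
parameters and exposes the fitted summaries as trailing-underscore
attributes; ``score(traces)`` evaluates the chosen likelihood (KF or RE) at
the posterior medians.  ``get_params``/``set_params`` come from
``sklearn.base.BaseEstimator`` so the estimator composes with sklearn
tooling (cloning, grid search over e.g. ``method``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .diagnose import improper_posterior_flag
from .infer import ParameterModel, UniformPrior, sample_posterior
from .kalman import loglik_traceset
from .re_baseline import re_loglik_traceset
from .schemes import KineticScheme
from .simulate import NoiseParams, TraceSet

__all__ = ["KineticModelEstimator"]


class KineticModelEstimator(BaseEstimator):
    """Bayesian estimator of kinetic-scheme rate constants from trace sets.

    Parameters
    ----------
    scheme : KineticScheme
        Channel model topology.
    free : list of rate/noise parameter names to infer (default: all rates).
    priors : dict name -> prior; defaults to uniform on (true/100, true*100)
        around the scheme's shipped default rates.
    method : 'kf' (generalized Kalman filter) or 're' (rate-equation
        baseline) likelihood.
    noise, Nch : fixed observation-noise parameters and channel count.
    backend, n_walkers, n_steps, n_burn, random_state : sampler settings.

    Attributes (after fit)
    ----------------------
    posterior_ : PosteriorSamples
    medians_ : dict of marginal posterior medians (point estimate)
    hdci_ : dict of 0.95 highest-density credible intervals
    improper_ : bool, sample-based improper-posterior flag
    """

    def __init__(
        self,
        scheme: KineticScheme = None,
        free=None,
        priors=None,
        method: str = "kf",
        noise: NoiseParams = None,
        Nch: float = 1000.0,
        backend: str = "emcee",
        n_walkers=None,
        n_steps: int = 400,
        n_burn: int = 400,
        random_state: int = 0,
    ):
        self.scheme = scheme
        self.free = free
        self.priors = priors
        self.method = method
        self.noise = noise
        self.Nch = Nch
        self.backend = backend
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.random_state = random_state

    def _model(self) -> ParameterModel:
        if self.scheme is None:
            raise ValueError("scheme is required")
        free = list(self.free) if self.free is not None else list(self.scheme.rate_names)
        priors = dict(self.priors) if self.priors is not None else {}
        for name in free:
            if name not in priors:
                ref = self.scheme.default_rates.get(name)
                if ref is None:
                    raise ValueError(f"no prior and no default rate for {name!r}")
                priors[name] = UniformPrior(ref / 100.0, ref * 100.0)
        fixed_rates = {
            n: v for n, v in self.scheme.default_rates.items() if n not in free
        }
        return ParameterModel(
            scheme=self.scheme,
            free=free,
            priors=priors,
            fixed_rates=fixed_rates,
            fixed_noise=self.noise if self.noise is not None else NoiseParams(),
            fixed_Nch=float(self.Nch),
        )

    def fit(self, X: TraceSet, y=None):
        """Sample the posterior from a TraceSet; returns self."""
        if not isinstance(X, TraceSet):
            raise TypeError("X must be a patchkf TraceSet")
        model = self._model()
        self.model_ = model
        self.posterior_ = sample_posterior(
            X,
            model,
            method=self.method,
            backend=self.backend,
            n_walkers=self.n_walkers,
            n_steps=self.n_steps,
            n_burn=self.n_burn,
            seed=self.random_state,
        )
        self.medians_ = self.posterior_.median()
        self.hdci_ = {n: self.posterior_.hdci(n, 0.95) for n in model.free}
        lo, hi = model.sampling_box()
        finite = np.isfinite(lo) & np.isfinite(hi)
        self.improper_ = bool(
            finite.any()
            and improper_posterior_flag(
                self.posterior_.draws[:, finite], lo[finite], hi[finite]
            )
        )
        return self

    def score(self, X: TraceSet, y=None) -> float:
        """Log-likelihood of a TraceSet at the fitted posterior medians."""
        if not hasattr(self, "medians_"):
            raise AttributeError("estimator is not fitted")
        rates, noise, Nch = self.model_.build(
            np.array([self.medians_[n] for n in self.model_.free])
        )
        run = loglik_traceset if self.method == "kf" else re_loglik_traceset
        return run(self.scheme, rates, noise, Nch, X).loglik
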