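"""Bayesian posterior sampling over kinetic-scheme parameters.

The posterior combines the Kalman-filter (or rate-equation) likelihood with
independent per-parameter priors.  Positive parameters (rates, channel
count, noise scales) are sampled on the log scale internally, with the
user-declared prior applied on the natural scale and the Jacobian included;
the default prior is uniform on the natural scale.

Microscopic reversibility for schemes with cycles is enforced softly by a
hierarchical prior: one loop rate is derived from the others via

    k_derived = R * (0.995 + 0.01 * k_star),      k_star ~ Beta(100.01, 100.01)

where R is the value that balances the cycle exactly, which constrains the
loop imbalance to a +/-0.005 relative band.

Sampling backends are pluggable: an affine-invariant ensemble sampler
(emcee) by default, or a self-contained adaptive random-walk Metropolis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .schemes import KineticScheme, loop_imbalance  # noqa: F401  (re-exported check)
from .simulate import NoiseParams, TraceSet

__all__ = [
    "UniformPrior",
    "NormalPrior",
    "GammaPrior",
    "BetaPrior",
    "ParameterModel",
    "PosteriorSamples",
    "micro_reversibility_transform",
    "log_posterior",
    "sample_posterior",
]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniformPrior:
    lo: float
    hi: float

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -np.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng) -> float:
        return float(rng.uniform(self.lo, self.hi))

    @property
    def support(self) -> tuple[float, float]:
        return self.lo, self.hi


@dataclass(frozen=True)
class NormalPrior:
    mu: float
    sigma: float

    def logpdf(self, x: float) -> float:
        return float(stats.norm.logpdf(x, self.mu, self.sigma))

    def sample(self, rng) -> float:
        return float(rng.normal(self.mu, self.sigma))

    @property
    def support(self) -> tuple[float, float]:
        return -np.inf, np.inf


@dataclass(frozen=True)
class GammaPrior:
    """Shape/rate parametrization: mean = shape / rate."""

    shape: float
    rate: float

    def logpdf(self, x: float) -> float:
        return float(stats.gamma.logpdf(x, self.shape, scale=1.0 / self.rate))

    def sample(self, rng) -> float:
        return float(rng.gamma(self.shape, 1.0 / self.rate))

    @property
    def support(self) -> tuple[float, float]:
        return 0.0, np.inf


@dataclass(frozen=True)
class BetaPrior:
    a: float = 100.01
    b: float = 100.01

    def logpdf(self, x: float) -> float:
        return float(stats.beta.logpdf(x, self.a, self.b))

    def sample(self, rng) -> float:
        return float(rng.beta(self.a, self.b))

    @property
    def support(self) -> tuple[float, float]:
        return 0.0, 1.0


# ---------------------------------------------------------------------------
# micro-reversibility
# ---------------------------------------------------------------------------


def micro_reversibility_transform(
    scheme: KineticScheme,
    rates: dict[str, float],
    k_star: float,
    derived: str,
    loop_index: int = 0,
) -> dict[str, float]:
    """Complete the rate set by deriving one loop rate from the others.

    ``k_derived = R * (0.995 + 0.01 * k_star)`` with R the ratio of the
    opposite-direction to same-direction rate products around the declared
    cycle, so the completed set has loop imbalance in [0.995, 1.005].
    The map (free rates, k_star) -> completed set is a bijection on the band.
    """
    if not 0.0 <= k_star <= 1.0:
        raise ValueError("k_star must lie in [0, 1]")
    loop = scheme.loops[loop_index]
    fwd, rev = [], []
    for a, b in zip(loop, loop[1:] + loop[:1]):
        fwd.append(scheme.find_edge(a, b).name)
        rev.append(scheme.find_edge(b, a).name)
    if derived in fwd:
        same, opposite = fwd, rev
    elif derived in rev:
        same, opposite = rev, fwd
    else:
        raise ValueError(f"{derived!r} is not an edge of loop {loop}")
    num = float(np.prod([rates[n] for n in opposite]))
    den = float(np.prod([rates[n] for n in same if n != derived]))
    if den == 0.0:
        raise ValueError("zero rate in the loop denominator")
    out = dict(rates)
    out[derived] = (num / den) * (0.995 + 0.01 * k_star)
    return out


# ---------------------------------------------------------------------------
# parameter model
# ---------------------------------------------------------------------------

_NOISE_FIELDS = ("i", "sigma_m", "sigma_op", "lambda_b", "sigma_back")


@dataclass
class ParameterModel:
    """Free/fixed split of the full parameter vector theta plus priors.

    Free parameters may be rate constants, ``Nch`` and any noise field; each
    free parameter needs a prior.  With ``micro_rev_derived`` set, that rate
    is not free: it is completed from the free parameter ``k_star`` through
    the micro-reversibility transform.
    """

    scheme: KineticScheme
    free: list[str]
    priors: dict[str, object]
    fixed_rates: dict[str, float] = field(default_factory=dict)
    fixed_noise: NoiseParams = field(default_factory=NoiseParams)
    fixed_Nch: float | None = None
    micro_rev_derived: str | None = None
    micro_rev_loop: int = 0

    def __post_init__(self):
        for name in self.free:
            if name not in self.priors:
                raise ValueError(f"free parameter {name!r} has no prior")
        if self.micro_rev_derived is not None and "k_star" not in self.free:
            raise ValueError("micro-reversibility requires a free 'k_star'")

    @property
    def dim(self) -> int:
        return len(self.free)

    def _is_log_scale(self, name: str) -> bool:
        return name != "k_star"

    def build(self, theta: np.ndarray):
        """Natural-scale vector -> (rates, noise, Nch)."""
        vals = dict(zip(self.free, np.asarray(theta, dtype=float)))
        rates = dict(self.fixed_rates)
        noise_kw = {}
        Nch = self.fixed_Nch
        for name, v in vals.items():
            if name == "Nch":
                Nch = v
            elif name in _NOISE_FIELDS:
                noise_kw[name] = v
            elif name == "k_star":
                pass
            else:
                rates[name] = v
        if self.micro_rev_derived is not None:
            rates = micro_reversibility_transform(
                self.scheme, rates, vals["k_star"], self.micro_rev_derived,
                self.micro_rev_loop,
            )
        noise = replace(self.fixed_noise, **noise_kw) if noise_kw else self.fixed_noise
        return rates, noise, Nch

    def log_prior(self, theta: np.ndarray) -> float:
        lp = 0.0
        for name, v in zip(self.free, np.asarray(theta, dtype=float)):
            lo, hi = self.priors[name].support
            if not (lo <= v <= hi):
                return -np.inf
            lp += self.priors[name].logpdf(v)
        return lp

    def sample_prior(self, rng) -> np.ndarray:
        return np.array([self.priors[n].sample(rng) for n in self.free])

    def to_internal(self, theta: np.ndarray) -> np.ndarray:
        return np.array(
            [
                np.log(v) if self._is_log_scale(n) else v
                for n, v in zip(self.free, theta)
            ]
        )

    def from_internal(self, x: np.ndarray) -> np.ndarray:
        return np.array(
            [
                np.exp(v) if self._is_log_scale(n) else v
                for n, v in zip(self.free, x)
            ]
        )

    def sampling_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Natural-scale prior-support bounds per free parameter."""
        lo = np.array([self.priors[n].support[0] for n in self.free])
        hi = np.array([self.priors[n].support[1] for n in self.free])
        return lo, hi


def log_posterior(
    theta: np.ndarray,
    traces: TraceSet,
    model: ParameterModel,
    method: str = "kf",
    use_likelihood: bool = True,
) -> float:
    """Log posterior (up to the evidence) at a natural-scale theta.

    Deterministic in theta; returns -inf outside the prior support.  With
    ``use_likelihood=False`` the target reduces to the prior (for sampler
    validation).
    """
    lp = model.log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    if not use_likelihood:
        return lp
    rates, noise, Nch = model.build(theta)
    if Nch is None or Nch <= 0:
        return -np.inf
    if any(v < 0 for v in rates.values()):
        return -np.inf
    if method == "kf":
        from .kalman import loglik_traceset as run
    elif method == "re":
        from .re_baseline import re_loglik_traceset as run
    else:
        raise ValueError("method must be 'kf' or 're'")
    try:
        ll = run(model.scheme, rates, noise, Nch, traces).loglik
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    return lp + ll


# ---------------------------------------------------------------------------
# posterior samples container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Labeled posterior draws with chain metadata."""

    draws: np.ndarray  # (S, dim), natural scale
    names: list[str]
    chain: np.ndarray  # (S,)
    seed: int
    backend: str
    acceptance: float = np.nan

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def median(self) -> dict[str, float]:
        """Marginal posterior medians (the package's standard point estimate)."""
        med = np.median(self.draws, axis=0)
        return dict(zip(self.names, med.tolist()))

    def hdci(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        from .diagnose import hdci as _hdci

        return _hdci(self[name], mass)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=self.names)
        df["chain"] = self.chain
        return df


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _init_walkers(model, traces, method, use_likelihood, n_walkers, rng):
    """Prior draws mapped to the internal (log) scale, retried until finite."""
    p0 = np.empty((n_walkers, model.dim))
    for w in range(n_walkers):
        for _ in range(200):
            theta = model.sample_prior(rng)
            if np.isfinite(
                log_posterior(theta, traces, model, method, use_likelihood)
            ):
                p0[w] = model.to_internal(theta)
                break
        else:
            raise RuntimeError("could not initialize walkers at finite posterior")
    return p0


def _ball_init(model, traces, method, use_likelihood, n_walkers, rng):
    """Small-ball walker initialization around a rough posterior mode.

    Ensemble samplers mix poorly when walkers start dispersed over a broad
    prior against a sharply concentrated likelihood; the standard remedy is
    a derivative-free mode search followed by a tight Gaussian ball.  For
    low-dimensional models a Nelder-Mead start from the best prior draw
    suffices; richer schemes develop separated local modes (e.g. a
    fast-gating mode that matches the mean relaxation but not the
    fluctuations), so a seeded differential-evolution search over the prior
    box is used before the local polish.
    """
    from scipy.optimize import differential_evolution, minimize

    def neg_lp(x):
        return -_log_post_internal(x, traces, model, method, use_likelihood)

    cand = _init_walkers(model, traces, method, use_likelihood, max(n_walkers, 16), rng)
    lps = np.array([-neg_lp(x) for x in cand])
    best_x, best_f = cand[int(np.argmax(lps))], -lps.max()
    if model.dim >= 4:
        lo, hi = model.sampling_box()
        bounds = []
        for j, name in enumerate(model.free):
            if model._is_log_scale(name):
                l = np.log(lo[j]) if lo[j] > 0 else cand[:, j].min() - 3.0
                h = np.log(hi[j]) if np.isfinite(hi[j]) else cand[:, j].max() + 3.0
                bounds.append((l, h))
            else:
                bounds.append((lo[j], hi[j]))
        de = differential_evolution(
            neg_lp,
            bounds,
            seed=int(rng.integers(0, 2**31 - 1)),
            maxiter=40,
            popsize=10,
            tol=1e-8,
            init="sobol",
            polish=False,
        )
        if np.isfinite(de.fun) and de.fun < best_f:
            best_x, best_f = de.x, de.fun
    res = minimize(
        neg_lp,
        best_x,
        method="Nelder-Mead",
        options={"maxfev": 300 * model.dim, "xatol": 1e-3, "fatol": 1e-2},
    )
    if np.isfinite(res.fun) and res.fun < best_f:
        best_x, best_f = res.x, res.fun
    centre = best_x
    p0 = np.empty((n_walkers, model.dim))
    for w in range(n_walkers):
        for _ in range(200):
            x = centre + 0.02 * rng.standard_normal(model.dim)
            if np.isfinite(
                _log_post_internal(x, traces, model, method, use_likelihood)
            ):
                p0[w] = x
                break
        else:
            raise RuntimeError("could not initialize walkers at finite posterior")
    return p0


def _log_post_internal(x, traces, model, method, use_likelihood):
    theta = model.from_internal(x)
    lp = log_posterior(theta, traces, model, method, use_likelihood)
    if not np.isfinite(lp):
        return -np.inf
    # Jacobian of the log transform for positive parameters
    jac = sum(xi for n, xi in zip(model.free, x) if model._is_log_scale(n))
    return lp + jac


def _sample_emcee(model, traces, method, use_likelihood, n_walkers, n_steps, n_burn, seed):
    import emcee

    rng = np.random.default_rng(seed)
    if use_likelihood:
        p0 = _ball_init(model, traces, method, use_likelihood, n_walkers, rng)
    else:
        p0 = _init_walkers(model, traces, method, use_likelihood, n_walkers, rng)
    sampler = emcee.EnsembleSampler(
        n_walkers,
        model.dim,
        _log_post_internal,
        args=(traces, model, method, use_likelihood),
    )
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, n_burn + n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)  # (n_steps, n_walkers, dim)
    acc = float(np.mean(sampler.acceptance_fraction))
    draws = chain.reshape(-1, model.dim)
    chain_ids = np.tile(np.arange(n_walkers), chain.shape[0])
    return draws, chain_ids, acc


def _sample_metropolis(
    model, traces, method, use_likelihood, n_chains, n_steps, n_burn, seed
):
    rng = np.random.default_rng(seed)
    draws_all, chain_ids = [], []
    n_acc_tot = 0
    for c in range(n_chains):
        x = _init_walkers(model, traces, method, use_likelihood, 1, rng)[0]
        lp = _log_post_internal(x, traces, model, method, use_likelihood)
        step = np.full(model.dim, 0.1)
        kept = np.empty((n_steps, model.dim))
        n_acc = 0
        for it in range(n_burn + n_steps):
            for d in range(model.dim):  # component-wise random walk
                prop = x.copy()
                prop[d] += step[d] * rng.standard_normal()
                lp_prop = _log_post_internal(
                    prop, traces, model, method, use_likelihood
                )
                accept = np.log(rng.random()) < lp_prop - lp
                if accept:
                    x, lp = prop, lp_prop
                if it < n_burn:  # Robbins-Monro adaptation toward ~0.35
                    step[d] *= np.exp((1.0 if accept else -0.5) * 0.5 / (1 + it) ** 0.6)
                elif accept:
                    n_acc += 1
            if it >= n_burn:
                kept[it - n_burn] = x
        draws_all.append(kept)
        chain_ids.append(np.full(n_steps, c))
        n_acc_tot += n_acc
    draws = np.vstack(draws_all)
    acc = n_acc_tot / (n_chains * n_steps * model.dim)
    return draws, np.concatenate(chain_ids), acc


def sample_posterior(
    traces: TraceSet,
    model: ParameterModel,
    method: str = "kf",
    backend: str = "emcee",
    n_walkers: int | None = None,
    n_steps: int = 500,
    n_burn: int = 500,
    seed: int = 0,
    use_likelihood: bool = True,
) -> PosteriorSamples:
    """Draw posterior samples of the free parameters.

    Identical seeds and backends give identical draws.  ``backend='emcee'``
    uses the affine-invariant ensemble sampler (``n_walkers`` chains,
    default ``max(2*dim+2, 8)``); ``backend='metropolis'`` uses the built-in
    adaptive component-wise random walk.
    """
    if n_walkers is None:
        n_walkers = max(2 * model.dim + 2, 8)
    if backend == "emcee":
        draws_int, chain_ids, acc = _sample_emcee(
            model, traces, method, use_likelihood, n_walkers, n_steps, n_burn, seed
        )
    elif backend == "metropolis":
        draws_int, chain_ids, acc = _sample_metropolis(
            model, traces, method, use_likelihood, n_walkers, n_steps, n_burn, seed
        )
    else:
        raise ValueError("backend must be 'emcee' or 'metropolis'")
    draws = np.vstack([model.from_internal(x) for x in draws_int])
    return PosteriorSamples(
        draws=draws,
        names=list(model.free),
        chain=chain_ids,
        seed=seed,
        backend=backend,
        acceptance=acc,
    )
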