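# patchkf

Bayesian inference of ion-channel kinetic schemes from macroscopic
patch-clamp (PC) and confocal patch-clamp fluorometry (cPCF) recordings,
built around a **generalized Kalman filter with state-dependent observation
noise**.

## The problem

The gating of a ligand-gated channel is modelled by a kinetic scheme: a
continuous-time Markov model with rate matrix K, where binding steps scale
with the ligand concentration L.  A patch contains an ensemble of Nch
independent channels, and the recorded current (and, in cPCF, the
ligand-binding fluorescence) is a low-dimensional, noisy projection of the
hidden occupancy count vector n(t).  Classical rate-equation (RE) fitting
propagates only the deterministic mean and treats every sample as
independent — it discards the autocorrelated intrinsic fluctuations of a
finite ensemble, which biases estimates and makes credible intervals far
too narrow.

`patchkf` instead tracks the first two moments of n(t) exactly through the
generalized-multinomial transition law,

    n̄(t+1) = T n̄(t),      T = exp(K Δt)
    P(t+1)  = Q(T, n̄) + T P Tᵀ,     Q = diag(T n̄) − T diag(n̄) Tᵀ,

and corrects them with each data point via the conjugate-normal update with
gain G = P Hᵀ S⁻¹, S = H P Hᵀ + Σ(n̄).  The noise covariance Σ is
*state-dependent* — open-channel excess noise σ_op² n_open on the current
and Poisson photon-counting variance λ_b·bound(t) on the fluorescence —
evaluated at the one-step prior mean by a total-variance argument, so the
per-point marginal likelihood N(y | H n̄, S) remains exact in its first two
moments.  The product of these marginals is the trace likelihood used for
posterior sampling over the rates, with an optional hierarchical prior that
softly enforces microscopic reversibility around cycles
(k = R·(0.995 + 0.01 k*), k* ~ Beta(100.01, 100.01)).

The package also ships the exact stochastic ensemble simulator (summed-CME
Gillespie with the full noise stack, Bessel filtering and
finite-integration-time windowing), the RE baseline likelihood for
comparison, and the evaluation machinery: normalized residuals and
autocorrelation, highest-density credible intervals/volumes by two methods,
binomial coverage calibration, and a/√Nch error-scaling fits.

## Worked example

```python
import numpy as np
from patchkf import (
    ccco, simulate_traceset, NoiseParams, KineticModelEstimator,
)
from patchkf.diagnose import normalized_residuals

scheme = ccco()                       # C1 <-> C2 <-> C3 <-> O4
noise = NoiseParams(i=1.0, sigma_m=1.0, sigma_op=np.sqrt(0.1), lambda_b=0.375)
traces = simulate_traceset(scheme, concentrations=[1.0, 8.0, 64.0],
                           Nch=1000, noise=noise, seed=0, f_ana=250.0)

est = KineticModelEstimator(scheme=scheme, method="kf", noise=noise,
                            Nch=1000, n_steps=150, n_burn=200,
                            random_state=0).fit(traces)
print({k: round(v, 1) for k, v in est.medians_.items()})
print("0.95 HDCI k34:", tuple(round(x, 1) for x in est.hdci_["k34"]))

rs = normalized_residuals(traces, scheme.default_rates, noise, 1000, scheme, "kf")
print("residual variance:", round(rs.variance(), 3))
```

prints (seed 0):

```
{'k12': 9.8, 'k21': 10.0, 'k23': 10.8, 'k32': 20.5, 'k34': 95.3, 'k43': 47.9}
0.95 HDCI k34: (86.8, 104.3)
residual variance: 0.979
```

The posterior medians recover the generating rates (k12 = 10 µM⁻¹s⁻¹,
k21 = 10 s⁻¹, …, k34 = 100 s⁻¹, k43 = 50 s⁻¹) to within a few percent, the
0.95 highest-density interval covers the true opening rate, and filtering
at the true parameters leaves unit-variance white residuals — the model
captures the signal up to its predicted dispersion.

A thin CLI wraps the same library:

```bash
patchkf simulate --scheme ccco --nch 1000 --seed 1 --out data/
patchkf loglik   --scheme ccco --data data/ --method kf
patchkf fit      --scheme ccco --data data/ --method kf --iters 300 --out samples.csv
patchkf diagnose --scheme ccco --data data/
```

## Layout

| module | contents |
| --- | --- |
| `patchkf.schemes` | kinetic schemes, rate/transition matrices, equilibria, loops |
| `patchkf.simulate` | Gillespie ensemble simulator + measurement-noise stack |
| `patchkf.kalman` | the generalized Kalman filter (prediction, correction, likelihood) |
| `patchkf.re_baseline` | rate-equation comparison likelihood |
| `patchkf.infer` | priors, micro-reversibility transform, posterior sampling |
| `patchkf.diagnose` | residuals, HDCI/HDCV, coverage calibration, error scaling |
| `patchkf.estimators` | scikit-learn-style `KineticModelEstimator` (fit/score) |
| `patchkf.io`, `patchkf.cli` | text trace folders, parameter files, CLI |

See `docs/methods.md` for the model, assumptions, numerical choices and
limitations.
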