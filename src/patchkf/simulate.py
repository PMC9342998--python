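"""Synthetic patch-clamp (PC) and patch-clamp fluorometry (cPCF) data.

The simulator produces exact stochastic trajectories of an ensemble of
``Nch`` independent channels under piecewise-constant ligand concentration
protocols (ideal concentration jumps), then applies the measurement model:

* current:      ``y_curr = i * n_open + Normal(0, sigma_m^2 + n_open * sigma_op^2)``
  (instrumental noise plus open-channel excess noise),
* fluorescence: ``y_flu = Poisson(lambda_b * bound(t)) + Normal(0, sigma_back^2)``
  (photon counting of bound ligands plus background after reference
  subtraction),

optionally followed by an analog-style 4-pole Bessel low-pass on the current
and finite-integration-time windowing of the fluorescence.

The ensemble trajectory is simulated at the level of the summed chemical
master equation: the state is the count vector n(t) and each directed edge
j -> i fires with propensity ``n_j * k_ij``.  This is distributionally
identical to simulating Nch independent channels with the Doob-Gillespie
algorithm but costs O(events) instead of O(Nch * events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from numba import njit

from .schemes import KineticScheme, build_rate_matrix, equilibrium_distribution

__all__ = [
    "CONCENTRATIONS_UM",
    "Protocol",
    "NoiseParams",
    "OccupancySeries",
    "TraceSet",
    "jump_protocol",
    "gillespie_ensemble",
    "sample_generalized_multinomial",
    "observe_current",
    "observe_fluorescence",
    "bessel_filter",
    "integrate_window",
    "rescaled_brightness",
    "decimate",
    "simulate_traceset",
]

#: The standard 10-concentration jump protocol series (uM).
CONCENTRATIONS_UM = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 64.0)


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant ligand concentration protocol.

    ``segments`` is a list of (duration s, concentration uM).  ``L_init`` is
    the conditioning concentration before the first jump; the ensemble starts
    from its equilibrium occupancy at ``L_init``.
    """

    segments: tuple[tuple[float, float], ...]
    f_sim: float = 1.0e4
    L_init: float = 0.0

    def __post_init__(self):
        for dur, L in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if L < 0:
                raise ValueError("concentrations must be >= 0")
        if self.f_sim <= 0:
            raise ValueError("f_sim must be > 0")


def jump_protocol(
    L: float, t_on: float = 1.0, t_off: float = 1.0, f_sim: float = 1.0e4
) -> Protocol:
    """Activation/deactivation jump: 0 -> L for ``t_on`` s, then back to 0."""
    return Protocol(segments=((t_on, L), (t_off, 0.0)), f_sim=f_sim, L_init=0.0)


@dataclass(frozen=True)
class NoiseParams:
    """Observation-noise parameters (benchmark-condition defaults).

    i        : mean single-channel current (signal units)
    sigma_m  : instrumental current-noise SD
    sigma_op : per-open-channel excess-noise SD (variance sigma_op^2 * n_open)
    lambda_b : mean photons per bound ligand per analysis frame
    sigma_back : background-fluorescence SD (Gaussian stand-in for the
                 Skellam-distributed bulk-subtraction residue)
    """

    i: float = 1.0
    sigma_m: float = 1.0
    sigma_op: float = np.sqrt(0.1)
    lambda_b: float = 0.375
    sigma_back: float = 0.0

    def __post_init__(self):
        for name in ("i", "sigma_m", "sigma_op", "lambda_b", "sigma_back"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class OccupancySeries:
    """Sampled ensemble occupancy: ``n[k]`` channels per state at ``times[k]``."""

    times: np.ndarray
    n: np.ndarray  # (N, M) integer counts
    Nch: int
    seg_index: np.ndarray = None  # (N,) protocol segment of each sample

    @property
    def f_sample(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


@dataclass
class TraceSet:
    """Per-concentration observation time series plus sampling metadata.

    ``current``/``fluorescence`` are (N, C) arrays, one column per ligand
    concentration, on the shared ``times`` grid.  ``fluorescence`` is None
    for pure patch-clamp data.
    """

    times: np.ndarray
    concentrations: list[float]
    current: np.ndarray
    fluorescence: np.ndarray | None = None
    f_ana: float = None
    f_sim: float = None
    f_cut: float | None = None
    T_int: float = 0.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    Nch: int | None = None
    seed: int | None = None
    scheme_name: str = ""
    t_on: float | None = None

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError("times must be strictly increasing with uniform step")

    @property
    def n_obs(self) -> int:
        return 1 if self.fluorescence is None else 2

    @property
    def n_traces(self) -> int:
        return self.current.shape[1]

    def y(self, c_idx: int) -> np.ndarray:
        """Observation matrix (N, n_obs) for one concentration.

        Observable ordering is (fluorescence, current) when both are present.
        """
        if self.fluorescence is None:
            return self.current[:, c_idx : c_idx + 1]
        return np.column_stack(
            [self.fluorescence[:, c_idx], self.current[:, c_idx]]
        )


# ---------------------------------------------------------------------------
# exact stochastic simulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gillespie_core(n0, frm, to, seg_rates, seg_steps, dt, seed):  # pragma: no cover
    np.random.seed(seed)
    M = n0.shape[0]
    E = frm.shape[0]
    N = 1 + int(seg_steps.sum())
    occ = np.empty((N, M), np.int64)
    seg_of = np.empty(N, np.int64)
    n = n0.copy()
    occ[0] = n
    seg_of[0] = 0
    t = 0.0
    k = 1  # next grid index to fill
    t_seg_end = 0.0
    for s in range(seg_rates.shape[0]):
        rates = seg_rates[s]
        t_seg_end += seg_steps[s] * dt
        while True:
            a0 = 0.0
            for e in range(E):
                a0 += n[frm[e]] * rates[e]
            if a0 > 1e12:
                raise RuntimeError("rate overflow: expected waiting time < 1e-12 s")
            if a0 <= 0.0:
                t_next = t_seg_end
            else:
                t_next = t + np.random.exponential(1.0 / a0)
            # record all grid samples strictly before the next event
            lim = min(t_next, t_seg_end)
            while k < N and k * dt <= lim + 1e-12 * dt:
                occ[k] = n
                seg_of[k] = s
                k += 1
            if t_next >= t_seg_end:
                # no event before the jump; memorylessness lets us restart
                t = t_seg_end
                break
            t = t_next
            u = np.random.random() * a0
            acc = 0.0
            e_sel = E - 1
            for e in range(E):
                acc += n[frm[e]] * rates[e]
                if u < acc:
                    e_sel = e
                    break
            n[frm[e_sel]] -= 1
            n[to[e_sel]] += 1
    return occ, seg_of


def gillespie_ensemble(
    scheme: KineticScheme,
    rates: dict[str, float],
    protocol: Protocol,
    Nch: int,
    seed: int | np.random.Generator,
    p0: np.ndarray | None = None,
) -> OccupancySeries:
    """Exact ensemble trajectory of Nch channels, sampled on the f_sim grid.

    The initial count vector is a multinomial draw from the equilibrium
    occupancy at ``protocol.L_init`` (or an explicit distribution ``p0``);
    concentration jumps are applied instantaneously at segment boundaries.
    """
    if Nch < 1:
        raise ValueError("Nch must be >= 1")
    rng = np.random.default_rng(seed)
    if p0 is None:
        p0 = equilibrium_distribution(build_rate_matrix(scheme, rates, protocol.L_init))
    n0 = rng.multinomial(Nch, p0).astype(np.int64)

    frm = np.array([e.frm - 1 for e in scheme.edges], dtype=np.int64)
    to = np.array([e.to - 1 for e in scheme.edges], dtype=np.int64)
    seg_rates = np.array(
        [
            [
                rates[e.name] * (L if e.ligand_order == 1 else 1.0)
                for e in scheme.edges
            ]
            for _, L in protocol.segments
        ],
        dtype=np.float64,
    )
    dt = 1.0 / protocol.f_sim
    seg_steps = np.array(
        [int(round(dur * protocol.f_sim)) for dur, _ in protocol.segments],
        dtype=np.int64,
    )
    core_seed = int(rng.integers(0, 2**31 - 1))
    occ, seg_of = _gillespie_core(n0, frm, to, seg_rates, seg_steps, dt, core_seed)
    times = np.arange(occ.shape[0]) * dt
    return OccupancySeries(times=times, n=occ, Nch=Nch, seg_index=seg_of)


def sample_generalized_multinomial(
    n: np.ndarray, T: np.ndarray, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw from the one-step transition distribution of the count vector.

    Each sub-population ``n[a]`` spreads independently as a multinomial with
    probabilities ``T[:, a]`` (column-stochastic T); the draws are summed.
    With ``size`` given, returns (size, M) independent one-step draws.
    """
    n = np.asarray(n, dtype=np.int64)
    M = n.shape[0]
    reps = 1 if size is None else int(size)
    out = np.zeros((reps, M), dtype=np.int64)
    for a in range(M):
        if n[a] > 0:
            out += rng.multinomial(n[a], T[:, a], size=reps)
    return out[0] if size is None else out


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------


def observe_current(
    occ: OccupancySeries,
    scheme: KineticScheme,
    noise: NoiseParams,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Current trace ``i * n_open + Normal(0, sigma_m^2 + n_open sigma_op^2)``."""
    rng = np.random.default_rng(seed)
    n_open = occ.n @ scheme.conducting_vector()
    var = noise.sigma_m**2 + n_open * noise.sigma_op**2
    return noise.i * n_open + rng.standard_normal(n_open.shape) * np.sqrt(var)


def observe_fluorescence(
    occ: OccupancySeries,
    scheme: KineticScheme,
    noise: NoiseParams,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Photon trace ``Poisson(lambda_b * bound(t)) + Normal(0, sigma_back^2)``."""
    rng = np.random.default_rng(seed)
    lam = noise.lambda_b * (occ.n @ scheme.bound_vector())
    y = rng.poisson(lam).astype(float)
    if noise.sigma_back > 0:
        y = y + rng.standard_normal(y.shape) * noise.sigma_back
    return y


def bessel_filter(
    y: np.ndarray, f_cut: float, fs: float, order: int = 4
) -> np.ndarray:
    """Single forward pass of a digital 4-pole low-pass Bessel filter.

    Emulates the analog anti-aliasing filter of a patch-clamp amplifier:
    unit DC gain, group delay *not* compensated (no backward pass), so the
    dynamics are distorted the way a real analog filter distorts them.
    """
    if f_cut >= fs / 2:
        raise ValueError("f_cut must be below the Nyquist frequency fs/2")
    sos = scipy.signal.bessel(order, f_cut, btype="low", fs=fs, output="sos")
    return scipy.signal.sosfilt(sos, y, axis=0)


def integrate_window(y: np.ndarray, T_int: float, fs: float) -> np.ndarray:
    """Non-overlapping window sums emulating finite frame-integration time.

    Sums ``m = T_int * fs`` consecutive samples (per-frame photon counts are
    summed as a Riemann approximation of the analog integral); the output
    sampling frequency is ``1/T_int``.  Keeping the signal-to-noise ratio
    constant across T_int (``lambda_b / T_int = const``) is the caller's
    responsibility, see :func:`rescaled_brightness`.
    """
    m_f = T_int * fs
    m = int(round(m_f))
    if abs(m_f - m) > 1e-9 or m < 1:
        raise ValueError("T_int must be a positive multiple of 1/fs")
    n_win = y.shape[0] // m
    if n_win < 1:
        raise ValueError("integration window longer than the trace")
    return y[: n_win * m].reshape(n_win, m, *y.shape[1:]).sum(axis=1)


def rescaled_brightness(noise: NoiseParams, T_int: float, T_ref: float) -> NoiseParams:
    """Scale lambda_b so that lambda_b / T_int stays constant w.r.t. T_ref."""
    return replace(noise, lambda_b=noise.lambda_b * T_int / T_ref)


def decimate(y: np.ndarray, f_from: float, f_to: float) -> np.ndarray:
    """Keep every (f_from/f_to)-th sample (plain subsampling, no averaging)."""
    stride_f = f_from / f_to
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9 or stride < 1:
        raise ValueError("f_from must be an integer multiple of f_to")
    return y[::stride]


# ---------------------------------------------------------------------------
# high-level generator
# ---------------------------------------------------------------------------


def simulate_traceset(
    scheme: KineticScheme,
    rates: dict[str, float] | None = None,
    concentrations=CONCENTRATIONS_UM,
    Nch: int = 1000,
    noise: NoiseParams | None = None,
    seed: int = 0,
    t_on: float = 1.0,
    t_off: float = 1.0,
    f_sim: float = 1.0e4,
    f_ana: float = 250.0,
    f_cut: float | None = None,
    with_fluorescence: bool = True,
) -> TraceSet:
    """Simulate the full study dataset: one concentration-jump trace per L.

    For every concentration the ensemble is simulated at ``f_sim``, current
    noise is added per simulation sample (Bessel-filtered at ``f_cut`` if
    requested) and the current is decimated to the analysis grid ``f_ana``;
    fluorescence photon counts are generated frame-wise directly on the
    analysis grid (``lambda_b`` is defined per analysis frame).
    """
    rates = dict(scheme.default_rates if rates is None else rates)
    noise = NoiseParams() if noise is None else noise
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(concentrations))
    curr_cols = []
    flu_cols = []
    for L, child in zip(concentrations, children):
        rng = np.random.default_rng(child)
        protocol = Protocol(segments=((t_on, L), (t_off, 0.0)), f_sim=f_sim, L_init=0.0)
        occ = gillespie_ensemble(scheme, rates, protocol, Nch, rng)
        y_curr = observe_current(occ, scheme, noise, rng)
        if f_cut is not None:
            y_curr = bessel_filter(y_curr, f_cut, f_sim)
        y_curr = decimate(y_curr, f_sim, f_ana)
        curr_cols.append(y_curr)
        if with_fluorescence:
            occ_ana = OccupancySeries(
                times=decimate(occ.times, f_sim, f_ana),
                n=decimate(occ.n, f_sim, f_ana),
                Nch=Nch,
            )
            flu_cols.append(observe_fluorescence(occ_ana, scheme, noise, rng))
    n_keep = min(len(c) for c in curr_cols)
    times = np.arange(n_keep) / f_ana
    return TraceSet(
        times=times,
        concentrations=list(concentrations),
        current=np.column_stack([c[:n_keep] for c in curr_cols]),
        fluorescence=(
            np.column_stack([c[:n_keep] for c in flu_cols]) if with_fluorescence else None
        ),
        f_ana=f_ana,
        f_sim=f_sim,
        f_cut=f_cut,
        T_int=0.0,
        noise=noise,
        Nch=Nch,
        seed=seed,
        scheme_name=scheme.name,
        t_on=t_on,
    )
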