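"""Kinetic schemes for ligand-gated ion channels.

A kinetic scheme is a finite-state continuous-time Markov model of a single
channel: a set of conformational/binding states connected by rate constants.
Binding transitions carry a pseudo-first-order ligand dependence, i.e. their
effective rate is (on-rate) * L with L the ligand concentration in uM and the
on-rate in uM^-1 s^-1.  All other rates are in s^-1.

State indexing is 1-based in user-facing configuration (C1, C2, ...) and
0-based internally (matrix rows/columns).  Rate parameters are named after
their directed edge: ``k12`` is the rate from state 1 to state 2.

The rate matrix convention follows the chemical master equation for a
column-stochastic propagator: ``K[i, j]`` (i != j) is the rate j -> i and the
diagonal closes each column to zero, so that ``T = expm(K * dt)`` is
column-stochastic and propagates probability vectors by ``p(t+dt) = T p(t)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import yaml
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Edge",
    "KineticScheme",
    "RateMatrix",
    "TransitionMatrix",
    "build_rate_matrix",
    "transition_matrix",
    "equilibrium_distribution",
    "eigenvalues",
    "loop_imbalance",
    "load_scheme",
    "ccco",
    "five_state_two_open",
    "six_state_loop",
]


@dataclass(frozen=True)
class Edge:
    """A directed transition ``frm -> to`` parametrized by rate ``name``.

    ``ligand_order`` is 0 for concentration-independent steps and 1 for
    binding steps whose rate is multiplied by the ligand concentration.
    """

    frm: int
    to: int
    name: str
    ligand_order: int = 0


@dataclass
class KineticScheme:
    """Topology and parametrization of a channel's rate matrix.

    Parameters
    ----------
    n_states
        Number of single-channel states M (states are labelled 1..M).
    edges
        Directed transitions; every edge references a rate-parameter name.
    conducting
        Map state -> mean single-channel current multiplier (0 or 1 here).
        Missing states default to 0.
    bound_ligands
        Map state -> number of bound ligands.  Missing states default to 0.
    loops
        Directed cycles (lists of 1-based states) used for the
        microscopic-reversibility constraint; the cycle ``[a, b, c]`` refers
        to the edges a->b->c->a (forward) and a->c->b->a (reverse).
    default_rates
        The shipped canonical parametrization used throughout the test bench.
    """

    n_states: int
    edges: list[Edge]
    conducting: dict[int, float] = field(default_factory=dict)
    bound_ligands: dict[int, int] = field(default_factory=dict)
    loops: list[list[int]] = field(default_factory=list)
    default_rates: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        names = set()
        for e in self.edges:
            if not (1 <= e.frm <= self.n_states and 1 <= e.to <= self.n_states):
                raise ValueError(f"edge {e.name}: states must lie in 1..{self.n_states}")
            if e.frm == e.to:
                raise ValueError(f"edge {e.name}: self-loops are not allowed")
            if e.ligand_order not in (0, 1):
                raise ValueError(f"edge {e.name}: ligand_order must be 0 or 1")
            if e.name in names:
                raise ValueError(f"duplicate rate-parameter name {e.name!r}")
            names.add(e.name)
            if e.ligand_order == 1:
                db = self.bound_ligands.get(e.to, 0) - self.bound_ligands.get(e.frm, 0)
                if db != 1:
                    raise ValueError(
                        f"binding edge {e.name}: bound-ligand count must increase by 1"
                    )
        for loop in self.loops:
            for a, b in zip(loop, loop[1:] + loop[:1]):
                if self.find_edge(a, b) is None or self.find_edge(b, a) is None:
                    raise ValueError(f"loop {loop}: missing edge between {a} and {b}")

    @property
    def rate_names(self) -> list[str]:
        return [e.name for e in self.edges]

    def find_edge(self, frm: int, to: int) -> Edge | None:
        for e in self.edges:
            if e.frm == frm and e.to == to:
                return e
        return None

    def conducting_vector(self) -> np.ndarray:
        """Single-channel current multiplier per state (0-based order)."""
        return np.array(
            [float(self.conducting.get(s, 0.0)) for s in range(1, self.n_states + 1)]
        )

    def bound_vector(self) -> np.ndarray:
        """Number of bound ligands per state (0-based order)."""
        return np.array(
            [float(self.bound_ligands.get(s, 0)) for s in range(1, self.n_states + 1)]
        )


@dataclass(frozen=True)
class RateMatrix:
    """Rate matrix K (s^-1) at a fixed ligand concentration L (uM)."""

    K: np.ndarray
    L: float

    @property
    def n_states(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic single-channel propagator for a step ``dt``."""

    T: np.ndarray
    dt: float


def build_rate_matrix(
    scheme: KineticScheme, rates: dict[str, float], L: float
) -> RateMatrix:
    """Assemble the rate matrix of ``scheme`` at ligand concentration ``L``.

    Binding-edge entries are scaled by L (pseudo-first-order kinetics); the
    diagonal closes each column to zero.
    """
    if L < 0:
        raise ValueError("ligand concentration must be >= 0")
    unknown = set(rates) - set(scheme.rate_names)
    if unknown:
        raise ValueError(f"unknown rate parameter(s): {sorted(unknown)}")
    M = scheme.n_states
    K = np.zeros((M, M))
    for e in scheme.edges:
        try:
            k = rates[e.name]
        except KeyError:
            raise ValueError(f"missing rate parameter {e.name!r}") from None
        if k < 0:
            raise ValueError(f"rate {e.name} must be >= 0, got {k}")
        K[e.to - 1, e.frm - 1] += k * (L if e.ligand_order == 1 else 1.0)
    K[np.diag_indices(M)] -= K.sum(axis=0)
    return RateMatrix(K=K, L=float(L))


def transition_matrix(K: RateMatrix | np.ndarray, dt: float) -> TransitionMatrix:
    """``T = expm(K * dt)`` via scaling-and-squaring Pade (scipy).

    T is column-stochastic: ``T[i, j]`` is the probability of a channel in
    state j to be found in state i after ``dt`` seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    T = scipy.linalg.expm(Kmat * dt)
    if not np.all(np.isfinite(T)):
        raise ValueError("matrix exponential produced non-finite entries")
    # expm can leave entries at -eps; clip and renormalize within tolerance
    T = np.clip(T, 0.0, None)
    colsum = T.sum(axis=0)
    if np.any(np.abs(colsum - 1.0) > 1e-8):
        raise ValueError("transition matrix columns do not sum to 1")
    return TransitionMatrix(T=T / colsum, dt=float(dt))


def equilibrium_distribution(K: RateMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution p with ``K p = 0``, ``sum(p) = 1``.

    For reducible chains (e.g. zero ligand concentration, where binding steps
    vanish) the stationary distribution restricted to the reachable recurrent
    class is returned if it is unique; otherwise the absorbing classes are
    reported in the error.
    """
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    ns = scipy.linalg.null_space(Kmat, rcond=1e-10)
    if ns.shape[1] == 1:
        v = ns[:, 0]
        v = v * np.sign(v.sum())
        if np.any(v < -1e-9 * max(np.abs(v).max(), 1.0)):
            raise ValueError("null vector has mixed signs; K is not a valid generator")
        p = np.clip(v, 0.0, None)
        return p / p.sum()
    # several recurrent classes: diagnose via strong connectivity of K > 0
    adj = (Kmat > 0).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    classes = [list(np.flatnonzero(labels == c) + 1) for c in range(n_comp)]
    raise ValueError(
        f"chain is reducible with {ns.shape[1]} recurrent classes; "
        f"strongly connected components (1-based states): {classes}"
    )


def eigenvalues(K: RateMatrix | np.ndarray) -> np.ndarray:
    """Real parts of the eigenvalues of K, sorted descending (s^-1).

    One eigenvalue is 0 (the equilibrium mode); the others are negative
    relaxation rates whose magnitudes set the time scales of the ensemble.
    """
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    re = np.real(np.linalg.eigvals(Kmat))
    return np.sort(re)[::-1]


def loop_imbalance(scheme: KineticScheme, rates: dict[str, float]) -> list[float]:
    """Ratio of forward to reverse rate products for each declared loop.

    A value of 1.0 means microscopic reversibility holds exactly around the
    cycle.  Ligand factors cancel provided both directions of the cycle carry
    the same total ligand order (guaranteed for physical binding cycles).
    """
    out = []
    for loop in scheme.loops:
        fwd = 1.0
        rev = 1.0
        for a, b in zip(loop, loop[1:] + loop[:1]):
            ef = scheme.find_edge(a, b)
            er = scheme.find_edge(b, a)
            if ef is None or er is None:
                raise ValueError(f"loop {loop}: undeclared edge between {a} and {b}")
            fwd *= rates[ef.name]
            rev *= rates[er.name]
        if rev == 0:
            raise ValueError(f"loop {loop}: zero rate in reverse product")
        out.append(fwd / rev)
    return out


# ---------------------------------------------------------------------------
# shipped schemes
# ---------------------------------------------------------------------------


def _scheme_from_dict(d: dict) -> KineticScheme:
    edges = [Edge(int(e[0]), int(e[1]), str(e[2]), int(e[3])) for e in d["edges"]]
    return KineticScheme(
        n_states=int(d["n_states"]),
        edges=edges,
        conducting={int(k): float(v) for k, v in d.get("conducting", {}).items()},
        bound_ligands={int(k): int(v) for k, v in d.get("bound_ligands", {}).items()},
        loops=[[int(s) for s in loop] for loop in d.get("loops", [])],
        default_rates={str(k): float(v) for k, v in d.get("default_rates", {}).items()},
        name=str(d.get("name", "")),
    )


def load_scheme(source) -> KineticScheme:
    """Load a scheme from a YAML file path or an open text stream."""
    if hasattr(source, "read"):
        d = yaml.safe_load(source)
    else:
        with open(source) as fh:
            d = yaml.safe_load(fh)
    return _scheme_from_dict(d)


def _load_shipped(fname: str) -> KineticScheme:
    ref = importlib.resources.files("patchkf.data").joinpath(fname)
    return _scheme_from_dict(yaml.safe_load(ref.read_text()))


def ccco() -> KineticScheme:
    """4-state model: two sequential ligand bindings and one opening step.

    C1 <-> C2 <-> C3 <-> O4, with C2 singly and C3/O4 doubly liganded.
    """
    return _load_shipped("ccco.yaml")


def five_state_two_open() -> KineticScheme:
    """5-state model with two open states branching off the binding chain."""
    return _load_shipped("five_state_two_open.yaml")


def six_state_loop() -> KineticScheme:
    """6-state model with a cycle, used with the micro-reversibility prior."""
    return _load_shipped("six_state_loop.yaml")
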