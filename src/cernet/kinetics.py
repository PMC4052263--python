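"""Mass-action kinetics of miRNA-target-complex systems.

A microRNA (R) and a target RNA (T) associate by diffusion-limited binding
into a complex (C) that is either unbound again or degraded.  The fraction
``alpha`` of complex-degradation events that also consume the miRNA is the
stoichiometric factor: ``alpha = 0`` is the catalytic limit (the miRNA is
recycled), ``alpha = 1`` the fully stoichiometric limit (miRNA and target
are degraded together).  For a single pair the levels obey

    dR/dt = g_R - b R T + u_C C + (1 - alpha) d_C C - d_R R
    dT/dt = g_T - b R T + u_C C - d_T T
    dC/dt = b R T - (u_C + d_C) C

and the same scheme extends to a chain of alternating miRNAs/targets or to
an arbitrary bipartite interaction network, with one complex species per
edge.  This module builds such systems, evaluates their right-hand side and
Jacobian, integrates them, finds steady states, and provides the closed-form
fixed points of the single pair and of the homogeneous circular chain.

Levels are dimensionless (arbitrary units); all rates are per second, the
binding rate ``b`` per (level * second).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "KineticParams",
    "DerivedParams",
    "BipartiteTopology",
    "ReactionSystem",
    "SystemState",
    "Trajectory",
    "pair_steady_state",
    "build_chain",
    "build_network",
    "rhs",
    "jacobian",
    "integrate",
    "steady_state",
    "chain_steady_state_closed_form",
    "perturb_generation_rate",
    "response_time",
    "relative_response_times",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class KineticParams:
    """Rate constants for one miRNA-target context.

    Attributes
    ----------
    g_R, g_T : generation rates of free miRNA / free target (level/s).
    b : miRNA-target binding rate (1/(level*s)).
    u_C : complex unbinding rate (1/s).
    d_R, d_T, d_C : degradation rates of free miRNA, free target and
        complex (1/s).
    alpha : stoichiometric factor in [0, 1]; fraction of complex
        degradation events that consume the miRNA.
    """

    g_R: float = 1.0
    g_T: float = 1.0
    b: float = 0.525
    u_C: float = 0.05
    d_R: float = 0.1
    d_T: float = 0.1
    d_C: float = 0.1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_R", "g_T", "b", "u_C", "d_R", "d_T", "d_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")

    @property
    def b_tilde(self) -> float:
        """Effective binding rate b*d_C/(u_C + d_C).

        The binding rate discounted by the probability that a formed
        complex dissociates instead of being degraded.  Zero when b is
        zero or the complex never degrades.
        """
        denom = self.u_C + self.d_C
        if denom == 0.0:
            return 0.0
        return self.b * self.d_C / denom

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedParams:
    """Composite parameters of the homogeneous-chain theory.

    ``p`` and ``q`` are the (negative) sensitivities of a miRNA to its
    neighbouring target and vice versa, evaluated at the circular-chain
    steady state; their product ``qp`` controls the decay of the
    correlation function.  ``X = b_tilde*g/(d_R*d_T)`` is the composite
    parameter of the equal-generation special case.
    """

    b_tilde: float
    p: float
    q: float
    X: float

    @property
    def qp(self) -> float:
        return self.p * self.q


# ---------------------------------------------------------------------------
# topology and reaction system

@dataclass(frozen=True)
class BipartiteTopology:
    """Undirected bipartite miRNA-mRNA interaction topology.

    Edges connect the two sides only; duplicate edges are rejected.
    """

    mirnas: tuple
    mrnas: tuple
    edges: tuple  # (mirna_id, mrna_id) pairs

    def __post_init__(self) -> None:
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValueError("duplicate miRNA ids")
        if len(set(self.mrnas)) != len(self.mrnas):
            raise ValueError("duplicate mRNA ids")
        mi, mr = set(self.mirnas), set(self.mrnas)
        if mi & mr:
            raise ValueError(f"ids shared between sides: {sorted(mi & mr)[:5]}")
        seen = set()
        for e in self.edges:
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            if e[0] not in mi or e[1] not in mr:
                raise ValueError(f"edge {e} does not connect miRNA side to mRNA side")

    @classmethod
    def from_edges(cls, edges) -> "BipartiteTopology":
        """Build from (mirna, mrna) pairs; node order follows first appearance."""
        mirnas, mrnas = [], []
        for r, t in edges:
            if r not in mirnas:
                mirnas.append(r)
            if t not in mrnas:
                mrnas.append(t)
        return cls(tuple(mirnas), tuple(mrnas), tuple((r, t) for r, t in edges))

    def degree(self, node) -> int:
        return sum(node in e for e in self.edges)


@dataclass
class ReactionSystem:
    """A bipartite mass-action reaction network with per-node/per-edge rates.

    State layout used throughout: ``y = [R (n_mirna), T (n_mrna), C (n_edge)]``.
    ``chain_index`` maps node id -> position ell along a chain (targets even,
    miRNAs odd) when the topology is a chain; otherwise None.
    """

    topology: BipartiteTopology
    g_R: np.ndarray  # per miRNA
    g_T: np.ndarray  # per mRNA
    d_R: np.ndarray
    d_T: np.ndarray
    b: np.ndarray  # per edge
    u_C: np.ndarray
    d_C: np.ndarray
    alpha: np.ndarray
    chain_index: dict | None = None
    boundary: str = "open"
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        nm, nt, ne = self.n_mirna, self.n_mrna, self.n_edges
        for name, arr, n in (
            ("g_R", self.g_R, nm), ("d_R", self.d_R, nm),
            ("g_T", self.g_T, nt), ("d_T", self.d_T, nt),
            ("b", self.b, ne), ("u_C", self.u_C, ne),
            ("d_C", self.d_C, ne), ("alpha", self.alpha, ne),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        # edge endpoint indices
        mi_index = {m: i for i, m in enumerate(self.topology.mirnas)}
        mr_index = {m: i for i, m in enumerate(self.topology.mrnas)}
        self._cache["ei"] = np.array(
            [mi_index[e[0]] for e in self.topology.edges], dtype=int)
        self._cache["ej"] = np.array(
            [mr_index[e[1]] for e in self.topology.edges], dtype=int)
        self._cache["mi_index"] = mi_index
        self._cache["mr_index"] = mr_index

    # -- basic dimensions ---------------------------------------------------
    @property
    def n_mirna(self) -> int:
        return len(self.topology.mirnas)

    @property
    def n_mrna(self) -> int:
        return len(self.topology.mrnas)

    @property
    def n_edges(self) -> int:
        return len(self.topology.edges)

    @property
    def n_state(self) -> int:
        return self.n_mirna + self.n_mrna + self.n_edges

    @property
    def edge_mirna_idx(self) -> np.ndarray:
        return self._cache["ei"]

    @property
    def edge_mrna_idx(self) -> np.ndarray:
        return self._cache["ej"]

    def node_index(self, node) -> tuple[str, int]:
        """Return ('R'|'T', within-side index) for a node id."""
        if node in self._cache["mi_index"]:
            return "R", self._cache["mi_index"][node]
        if node in self._cache["mr_index"]:
            return "T", self._cache["mr_index"][node]
        raise KeyError(f"unknown node {node!r}")

    def copy(self) -> "ReactionSystem":
        return ReactionSystem(
            topology=self.topology,
            g_R=self.g_R.copy(), g_T=self.g_T.copy(),
            d_R=self.d_R.copy(), d_T=self.d_T.copy(),
            b=self.b.copy(), u_C=self.u_C.copy(),
            d_C=self.d_C.copy(), alpha=self.alpha.copy(),
            chain_index=dict(self.chain_index) if self.chain_index else None,
            boundary=self.boundary,
        )


@dataclass(frozen=True)
class SystemState:
    """Levels of free miRNAs (R), free targets (T) and complexes (C)."""

    R: np.ndarray
    T: np.ndarray
    C: np.ndarray

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.R, self.T, self.C])

    @classmethod
    def from_vector(cls, system: ReactionSystem, y: np.ndarray) -> "SystemState":
        nm, nt = system.n_mirna, system.n_mrna
        return cls(R=np.array(y[:nm]), T=np.array(y[nm:nm + nt]),
                   C=np.array(y[nm + nt:]))

    def level(self, system: ReactionSystem, node) -> float:
        kind, i = system.node_index(node)
        return float(self.R[i] if kind == "R" else self.T[i])


@dataclass
class Trajectory:
    """Time course of a ReactionSystem integration."""

    t: np.ndarray
    states: np.ndarray  # (n_times, n_state)
    system: ReactionSystem
    converged: bool = False

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_vector(self.system, self.states[i])

    @property
    def final(self) -> SystemState:
        return self.state_at(len(self.t) - 1)

    def node_levels(self, node) -> np.ndarray:
        kind, i = self.system.node_index(node)
        nm = self.system.n_mirna
        col = i if kind == "R" else nm + i
        return self.states[:, col]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, node, species kind)."""
        rows = []
        nm, nt = self.system.n_mirna, self.system.n_mrna
        for k, t in enumerate(self.t):
            y = self.states[k]
            for i, node in enumerate(self.system.topology.mirnas):
                rows.append((t, node, "R", y[i]))
            for j, node in enumerate(self.system.topology.mrnas):
                rows.append((t, node, "T", y[nm + j]))
            for e, (r, s) in enumerate(self.system.topology.edges):
                rows.append((t, f"{r}|{s}", "C", y[nm + nt + e]))
        return pd.DataFrame(rows, columns=["time", "node_id", "species", "level"])


# ---------------------------------------------------------------------------
# closed forms

def pair_steady_state(params: KineticParams) -> SystemState:
    """Unique nonnegative fixed point of the single miRNA-target pair.

    Solves T = g_T/(d_T + bt*R), R = g_R/(d_R + alpha*bt*T) with
    bt = b*d_C/(u_C + d_C), which reduces to one quadratic in T.
    """
    if params.d_R <= 0 or params.d_T <= 0:
        raise ValueError("pair_steady_state requires d_R > 0 and d_T > 0")
    bt = params.b_tilde
    g_R, g_T, d_R, d_T, a = params.g_R, params.g_T, params.d_R, params.d_T, params.alpha
    if params.b == 0.0:
        R, T, C = g_R / d_R, g_T / d_T, 0.0
    elif bt == 0.0:
        # complexes form but are only unbound, never degraded: free levels decouple
        R, T = g_R / d_R, g_T / d_T
        denom = params.u_C + params.d_C
        C = params.b * R * T / denom if denom > 0 else np.inf
    elif a * bt == 0.0:  # catalytic miRNA: R unaffected by target
        R = g_R / d_R
        T = g_T / (d_T + bt * R)
        C = params.b * R * T / (params.u_C + params.d_C)
    else:
        # a*bt*d_T * T^2 + (d_R*d_T + bt*g_R - a*bt*g_T) * T - g_T*d_R = 0
        A = a * bt * d_T
        B = d_R * d_T + bt * g_R - a * bt * g_T
        Cc = -g_T * d_R
        T = (-B + np.sqrt(B * B - 4 * A * Cc)) / (2 * A)
        R = g_R / (d_R + a * bt * T)
        C = params.b * R * T / (params.u_C + params.d_C)
    return SystemState(R=np.array([R]), T=np.array([T]), C=np.array([C]))


def chain_steady_state_closed_form(params: KineticParams) -> tuple[float, float]:
    """Shared (R, T) fixed point of the homogeneous circular chain.

    Every miRNA sees two targets and vice versa, so the pair quadratic
    acquires a factor 2 on the binding terms:

        T = [-(2*bt*(g_R - a*g_T) + d_R*d_T)
             + sqrt((2*bt*(g_R - a*g_T) + d_R*d_T)^2 + 8*a*bt*g_T*d_R*d_T)]
            / (4*a*bt*d_T)
        R = g_R / (d_R + 2*a*bt*T)

    Also the fixed point of an open chain far from the boundaries.  The
    implementation uses the algebraically equivalent conjugate form, which
    passes smoothly through the catalytic limit alpha -> 0
    (T = g_T/(d_T + 2*bt*g_R/d_R), R = g_R/d_R) and through bt -> 0.
    """
    if params.d_T <= 0 or params.d_R <= 0:
        raise ValueError("requires positive degradation rates d_R, d_T")
    bt = params.b_tilde
    g_R, g_T, d_R, d_T, a = params.g_R, params.g_T, params.d_R, params.d_T, params.alpha
    # conjugate form of the quadratic root: equals
    # [-A + sqrt(A^2 + 8*a*bt*g_T*d_R*d_T)] / (4*a*bt*d_T) but stays finite
    # and cancellation-free as alpha -> 0 (catalytic limit) and bt -> 0
    A = 2 * bt * (g_R - a * g_T) + d_R * d_T
    T = 2 * g_T * d_R / (A + np.sqrt(A * A + 8 * a * bt * g_T * d_R * d_T))
    R = g_R / (d_R + 2 * a * bt * T)
    return R, T


# ---------------------------------------------------------------------------
# builders

def _homogeneous_arrays(params, n_pairs: int):
    if isinstance(params, KineticParams):
        return [params] * n_pairs
    params = list(params)
    if len(params) != n_pairs:
        raise ValueError(f"need {n_pairs} parameter sets, got {len(params)}")
    return params


def build_chain(N: int, params, boundary: str = "open") -> ReactionSystem:
    """Chain of 2N alternating RNA species: targets at even positions
    ell = 0, 2, ..., 2N-2 and miRNAs at odd positions ell = 1, 3, ..., 2N-1.

    Each interior miRNA at ell regulates the targets at ell-1 and ell+1;
    ``boundary='open'`` drops out-of-range neighbours, ``'circular'`` wraps
    (miRNA 2N-1 also regulates target 0).

    ``params`` is a single KineticParams applied everywhere or a sequence
    of N per-pair KineticParams; pair i supplies the rates of target 2i,
    miRNA 2i+1 and the edges emanating from miRNA 2i+1.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if boundary not in ("open", "circular"):
        raise ValueError(f"boundary must be 'open' or 'circular', got {boundary!r}")
    plist = _homogeneous_arrays(params, N)
    targets = [f"T{2 * i}" for i in range(N)]
    mirnas = [f"R{2 * i + 1}" for i in range(N)]
    edges, eparams = [], []
    for i in range(N):  # miRNA at ell = 2i+1, neighbours ell +- 1
        ell = 2 * i + 1
        for tpos in (ell - 1, ell + 1):
            if boundary == "circular":
                tpos = tpos % (2 * N)
            elif not (0 <= tpos <= 2 * N - 2):
                continue
            edge = (f"R{ell}", f"T{tpos}")
            if edge not in edges:  # N=1 circular would duplicate
                edges.append(edge)
                eparams.append(plist[i])
    topo = BipartiteTopology(tuple(mirnas), tuple(targets), tuple(edges))
    chain_index = {f"T{2 * i}": 2 * i for i in range(N)}
    chain_index.update({f"R{2 * i + 1}": 2 * i + 1 for i in range(N)})
    return ReactionSystem(
        topology=topo,
        g_R=np.array([p.g_R for p in plist]),
        g_T=np.array([p.g_T for p in plist]),
        d_R=np.array([p.d_R for p in plist]),
        d_T=np.array([p.d_T for p in plist]),
        b=np.array([p.b for p in eparams]),
        u_C=np.array([p.u_C for p in eparams]),
        d_C=np.array([p.d_C for p in eparams]),
        alpha=np.array([p.alpha for p in eparams]),
        chain_index=chain_index,
        boundary=boundary,
    )


def build_network(topology: BipartiteTopology, params: KineticParams,
                  generation_mode: str = "uniform",
                  base_rate: float | None = None) -> ReactionSystem:
    """Reaction system on an arbitrary bipartite topology.

    ``generation_mode='degree_proportional'`` assigns each node the
    generation rate base_rate * degree (hubs are transcribed more, an
    assumption used for dense subnetwork simulations);  ``'uniform'``
    gives every node base_rate.  base_rate defaults to the side's g in
    ``params``.  Isolated nodes under degree_proportional get zero
    generation (warned, kept).
    """
    if not topology.mirnas and not topology.mrnas:
        raise ValueError("topology is empty")
    if generation_mode not in ("uniform", "degree_proportional"):
        raise ValueError(f"unknown generation_mode {generation_mode!r}")
    deg = {n: 0 for n in topology.mirnas + topology.mrnas}
    for r, t in topology.edges:
        deg[r] += 1
        deg[t] += 1
    ne = len(topology.edges)
    if generation_mode == "uniform":
        g_R = np.full(len(topology.mirnas), base_rate if base_rate is not None else params.g_R)
        g_T = np.full(len(topology.mrnas), base_rate if base_rate is not None else params.g_T)
    else:
        base_r = base_rate if base_rate is not None else params.g_R
        base_t = base_rate if base_rate is not None else params.g_T
        g_R = np.array([base_r * deg[n] for n in topology.mirnas], dtype=float)
        g_T = np.array([base_t * deg[n] for n in topology.mrnas], dtype=float)
        isolated = [n for n in topology.mirnas + topology.mrnas if deg[n] == 0]
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated node(s) get zero generation under "
                f"degree_proportional mode: {isolated[:5]}")
    return ReactionSystem(
        topology=topology,
        g_R=g_R, g_T=g_T,
        d_R=np.full(len(topology.mirnas), params.d_R),
        d_T=np.full(len(topology.mrnas), params.d_T),
        b=np.full(ne, params.b), u_C=np.full(ne, params.u_C),
        d_C=np.full(ne, params.d_C), alpha=np.full(ne, params.alpha),
    )


def perturb_generation_rate(system: ReactionSystem, node, factor: float) -> ReactionSystem:
    """New system with ``node``'s generation rate multiplied by ``factor``."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    kind, i = system.node_index(node)  # raises KeyError for unknown node
    new = system.copy()
    if kind == "R":
        new.g_R[i] *= factor
    else:
        new.g_T[i] *= factor
    return new


# ---------------------------------------------------------------------------
# dynamics

def rhs(system: ReactionSystem, y: np.ndarray) -> np.ndarray:
    """Mass-action right-hand side over the packed state vector."""
    y = np.asarray(y, dtype=float)
    if y.shape != (system.n_state,):
        raise ValueError(f"state must have shape ({system.n_state},), got {y.shape}")
    nm, nt = system.n_mirna, system.n_mrna
    R, T, C = y[:nm], y[nm:nm + nt], y[nm + nt:]
    ei, ej = system.edge_mirna_idx, system.edge_mrna_idx
    flux = system.b * R[ei] * T[ej]
    backR = (system.u_C + (1.0 - system.alpha) * system.d_C) * C
    backT = system.u_C * C
    dR = system.g_R - system.d_R * R
    np.subtract.at(dR, ei, flux)
    np.add.at(dR, ei, backR)
    dT = system.g_T - system.d_T * T
    np.subtract.at(dT, ej, flux)
    np.add.at(dT, ej, backT)
    dC = flux - (system.u_C + system.d_C) * C
    return np.concatenate([dR, dT, dC])


def rhs_state(system: ReactionSystem, state: SystemState) -> SystemState:
    """rhs in SystemState form."""
    return SystemState.from_vector(system, rhs(system, state.to_vector()))


def jacobian(system: ReactionSystem, y: np.ndarray) -> np.ndarray:
    """Dense analytic Jacobian of :func:`rhs`."""
    nm, nt, ne = system.n_mirna, system.n_mrna, system.n_edges
    R, T = y[:nm], y[nm:nm + nt]
    ei, ej = system.edge_mirna_idx, system.edge_mrna_idx
    J = np.zeros((system.n_state, system.n_state))
    b, u, dC, a = system.b, system.u_C, system.d_C, system.alpha
    iR, iT, iC = np.arange(nm), nm + np.arange(nt), nm + nt + np.arange(ne)
    J[iR, iR] = -system.d_R
    J[iT, iT] = -system.d_T
    J[iC, iC] = -(u + dC)
    bT = b * T[ej]
    bR = b * R[ei]
    np.add.at(J, (ei, ei), -bT)          # d(dR_i)/dR_i from each edge
    np.add.at(J, (ei, nm + ej), -bR)
    np.add.at(J, (nm + ej, nm + ej), -bR)
    np.add.at(J, (nm + ej, ei), -bT)
    J[ei, iC] += u + (1.0 - a) * dC
    J[nm + ej, iC] += u
    J[iC, ei] = bT
    J[iC, nm + ej] = bR
    return J


def integrate(system: ReactionSystem, state0: SystemState | np.ndarray,
              t_end: float, rtol: float = 1e-9, atol: float = 1e-12,
              t_eval: np.ndarray | None = None,
              neg_tolerance: float = 1e-8) -> Trajectory:
    """Integrate the mass-action ODEs with a stiffness-switching solver.

    Small negative excursions (below ``-neg_tolerance``never reached) are
    clipped to zero in the returned states; a deeper excursion raises.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = state0.to_vector() if isinstance(state0, SystemState) else np.asarray(state0, float)
    sol = solve_ivp(
        lambda t, y: rhs(system, y), (0.0, t_end), y0,
        method="LSODA", jac=lambda t, y: jacobian(system, y),
        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}")
    states = sol.y.T
    low = states.min()
    if low < -neg_tolerance:
        raise RuntimeError(f"negative excursion {low} beyond tolerance")
    states = np.clip(states, 0.0, None)
    res = np.abs(rhs(system, states[-1]))
    scale = np.abs(states[-1])
    converged = bool(np.all(res < 1e-10 + 1e-8 * scale))
    return Trajectory(t=sol.t, states=states, system=system, converged=converged)


def _default_guess(system: ReactionSystem) -> np.ndarray:
    R = system.g_R / np.maximum(system.d_R, 1e-12)
    T = system.g_T / np.maximum(system.d_T, 1e-12)
    ei, ej = system.edge_mirna_idx, system.edge_mrna_idx
    C = system.b * R[ei] * T[ej] / np.maximum(system.u_C + system.d_C, 1e-12)
    return np.concatenate([R, T, C])


def steady_state(system: ReactionSystem, state0: SystemState | np.ndarray | None = None,
                 atol: float = 1e-10, rtol: float = 1e-8,
                 max_time: float = 1e6) -> SystemState:
    """Steady state of the network: Newton-type solve with relaxation fallback.

    Convergence criterion: ``max |rhs| < atol + rtol * level`` componentwise.
    Starts from ``state0`` or the decoupled g/d guess; if the algebraic
    solve fails or lands on a negative branch, relaxes by integration and
    retries.
    """
    if state0 is None:
        y0 = _default_guess(system)
    else:
        y0 = state0.to_vector() if isinstance(state0, SystemState) else np.asarray(state0, float)

    def ok(y: np.ndarray) -> bool:
        if y.min() < -1e-9:
            return False
        return bool(np.all(np.abs(rhs(system, y)) < atol + rtol * np.abs(y)))

    sol = root(lambda y: rhs(system, y), y0,
               jac=lambda y: jacobian(system, y), method="hybr",
               options={"xtol": 1e-13})
    if ok(sol.x):
        return SystemState.from_vector(system, np.clip(sol.x, 0.0, None))
    # fallback: relax toward the attractor, then polish
    t_end = 100.0
    y = np.clip(y0, 0.0, None)
    while t_end <= max_time:
        traj = integrate(system, y, t_end, rtol=1e-10, atol=1e-13)
        y = traj.states[-1]
        sol = root(lambda v: rhs(system, v), y,
                   jac=lambda v: jacobian(system, v), method="hybr",
                   options={"xtol": 1e-13})
        if ok(sol.x):
            return SystemState.from_vector(system, np.clip(sol.x, 0.0, None))
        if ok(y):
            return SystemState.from_vector(system, y)
        t_end *= 10.0
    res = np.max(np.abs(rhs(system, y)))
    raise RuntimeError(f"steady_state did not converge within t={max_time}; residual {res:.3e}")


# ---------------------------------------------------------------------------
# response times

def response_time(trajectory: Trajectory, node, old_level: float,
                  new_level: float) -> float:
    """First time the node's level crosses halfway between old and new level.

    Linear interpolation between samples; NaN (with a warning) if the
    midpoint is never crossed.
    """
    if old_level == new_level:
        raise ValueError("old and new levels must differ")
    levels = trajectory.node_levels(node)
    mid = 0.5 * (old_level + new_level)
    sgn = np.sign(levels - mid)
    sgn0 = np.sign(old_level - mid)
    crossed = np.nonzero(sgn != sgn0)[0]
    if len(crossed) == 0:
        warnings.warn(f"node {node!r} never crosses its midpoint level")
        return float("nan")
    k = crossed[0]
    if k == 0:
        return float(trajectory.t[0])
    t0, t1 = trajectory.t[k - 1], trajectory.t[k]
    y0, y1 = levels[k - 1], levels[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (mid - y0) * (t1 - t0) / (y1 - y0))


def relative_response_times(trajectory: Trajectory, source,
                            old: SystemState, new: SystemState,
                            nodes=None) -> dict:
    """Response times normalized by the source's; source maps to 1.0."""
    system = trajectory.system
    nodes = list(nodes) if nodes is not None else list(
        system.topology.mirnas + system.topology.mrnas)
    t_src = response_time(trajectory, source,
                          old.level(system, source), new.level(system, source))
    out = {}
    for node in nodes:
        t_n = response_time(trajectory, node,
                            old.level(system, node), new.level(system, node))
        out[node] = t_n / t_src
    return out
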