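"""Propagation of perturbation effects: correlation function and length.

A small steady-state perturbation of a source RNA propagates through the
alternating miRNA/target chain.  The correlation function

    C(ell) = (dT_ell / T_ell) / (dT_0 / T_0)

measures the normalized full response of the target at (even) distance
``ell`` from the perturbed source.  On a homogeneous chain C satisfies the
linear recurrence

    C(0) = 1,   C(ell) = qp * [C(ell+2) + 2 C(ell) + C(ell-2)],  ell >= 2

with p = -alpha*bt*g_R/(d_R + 2*alpha*bt*T)^2 and
q = -bt*g_T/(d_T + 2*bt*R)^2 evaluated at the circular-chain steady state
(so qp = p*q >= 0).  Its decaying solution is exponential,
C(ell) = exp(-ell/l0), with correlation length

    l0 = 1 / arcosh(1 / (2*sqrt(qp))),     valid for qp < 1/4.

This module provides the closed form, an independent brute-force linear
solve of the truncated recurrence, the equal-generation special case in
terms of X = bt*g/(d_R*d_T), numerical correlation profiles obtained by
actually perturbing and re-relaxing a simulated system, exponential fits,
parameter sweeps, and per-pair correlation matrices on arbitrary bipartite
networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .kinetics import (
    DerivedParams,
    KineticParams,
    ReactionSystem,
    SystemState,
    chain_steady_state_closed_form,
    perturb_generation_rate,
    steady_state,
)

__all__ = [
    "CorrelationProfile",
    "SweepResult",
    "derived_params",
    "correlation_length_closed_form",
    "qp_equal_generation",
    "recurrence_solve",
    "fit_correlation_length",
    "correlation_function_numerical",
    "parameter_sweep",
    "network_correlation_matrix",
]

LOG_FLOOR = 1e-10  # C(ell) values below this are numerical noise; excluded from fits


@dataclass
class CorrelationProfile:
    """C(ell) versus even distance ell from a perturbation source."""

    source: object
    distances: np.ndarray
    values: np.ndarray
    delta_fraction: float
    l0: float = float("nan")
    fit_residual: float = float("nan")
    fit_range: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": self.source,
            "distance": self.distances,
            "value": self.values,
        })


@dataclass
class SweepResult:
    """Correlation length across a parameter grid."""

    parameter: str
    grid: np.ndarray
    l0_analytic: np.ndarray
    l0_fitted: np.ndarray
    delta_g: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "parameter": self.parameter,
            "grid_value": self.grid,
            "l0_analytic": self.l0_analytic,
            "l0_fitted": self.l0_fitted,
        })
        if self.delta_g is not None:
            df["delta_g"] = self.delta_g
        return df


# ---------------------------------------------------------------------------
# analytic theory

def derived_params(params: KineticParams) -> DerivedParams:
    """p, q and X for the homogeneous chain, at its circular steady state."""
    bt = params.b_tilde
    R, T = chain_steady_state_closed_form(params)
    a = params.alpha
    p = -a * bt * params.g_R / (params.d_R + 2 * a * bt * T) ** 2
    q = -bt * params.g_T / (params.d_T + 2 * bt * R) ** 2
    X = bt * params.g_R / (params.d_R * params.d_T)
    return DerivedParams(b_tilde=bt, p=p, q=q, X=X)


def _l0_from_qp(qp: float) -> float:
    if qp == 0.0:
        return 0.0
    return float(1.0 / np.arccosh(1.0 / (2.0 * np.sqrt(qp))))


def correlation_length_closed_form(params: KineticParams) -> tuple[float, DerivedParams]:
    """Closed-form correlation length l0 = 1/arcosh(1/(2*sqrt(qp))).

    Raises when qp >= 1/4, outside the validity domain of the exponential
    solution of the recurrence.
    """
    dp = derived_params(params)
    qp = dp.qp
    if qp >= 0.25:
        raise ValueError(f"closed form valid only for qp < 1/4, got qp = {qp}")
    return _l0_from_qp(qp), dp


def qp_equal_generation(alpha: float, X: float) -> float:
    """qp of the equal-generation case g_R = g_T = g, X = bt*g/(d_R*d_T):

        1/sqrt(qp) = (1/(2*sqrt(alpha)*X)) * [1 + 2X(1+alpha)
                      + sqrt((2X(1-alpha) + 1)^2 + 8*alpha*X)]

    (The sqrt(alpha) in the prefactor follows from substituting the chain
    steady state into p*q; at alpha = 1 it is invisible.  Derived
    symbolically and checked against the raw-parameter route in the tests.)
    """
    if alpha <= 0 or X <= 0:
        raise ValueError("alpha and X must be > 0")
    inv_sqrt = (1.0 + 2 * X * (1 + alpha)
                + np.sqrt((2 * X * (1 - alpha) + 1) ** 2 + 8 * alpha * X)) \
        / (2 * np.sqrt(alpha) * X)
    return float(1.0 / inv_sqrt ** 2)


def recurrence_solve(qp: float, L: int, L_big: int | None = None) -> np.ndarray:
    """Brute-force decaying solution of the correlation recurrence.

    Solves the truncated linear system C(0)=1, C(L_big)=0,
    C(ell) = qp*[C(ell+2) + 2C(ell) + C(ell-2)] for even ell, as the
    independent oracle against the closed-form exponential.
    """
    if not 0.0 <= qp < 0.25:
        raise ValueError(f"recurrence decays only for 0 <= qp < 1/4, got {qp}")
    if L < 0 or L % 2:
        raise ValueError("L must be even and >= 0")
    if qp == 0.0:
        out = np.zeros(L // 2 + 1)
        out[0] = 1.0
        return out
    if L_big is None:
        # far boundary: deep enough that the truncation error at L is negligible
        l0 = _l0_from_qp(qp)
        L_big = max(4 * L + 40, int(np.ceil(40 * l0 / 2) * 2) + L)
    m = L_big // 2 - 1  # unknowns C(2), C(4), ..., C(L_big - 2)
    # qp*C(ell+2) + (2*qp - 1)*C(ell) + qp*C(ell-2) = 0
    ab = np.zeros((3, m))
    ab[0, 1:] = qp          # superdiagonal
    ab[1, :] = 2 * qp - 1.0  # diagonal
    ab[2, :-1] = qp          # subdiagonal
    bvec = np.zeros(m)
    bvec[0] = -qp  # from C(0) = 1
    C = solve_banded((1, 1), ab, bvec)
    return np.concatenate(([1.0], C))[: L // 2 + 1]


def fit_correlation_length(profile: CorrelationProfile | None = None, *,
                           distances: np.ndarray | None = None,
                           values: np.ndarray | None = None,
                           floor: float = LOG_FLOOR) -> float:
    """Least-squares exponential fit C(ell) ~ exp(-ell/l0) on even distances.

    Fits log C against ell over the points above ``floor``; requires at
    least 3 usable points.  Updates and returns the profile's ``l0`` when
    a profile is given.
    """
    if profile is not None:
        distances, values = profile.distances, profile.values
    distances = np.asarray(distances, float)
    values = np.asarray(values, float)
    usable = values > floor
    if usable.sum() < 3:
        raise ValueError(f"need >= 3 points above floor {floor}, have {usable.sum()}")
    x, y = distances[usable], np.log(values[usable])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("profile does not decay; cannot fit a correlation length")
    l0 = -1.0 / slope
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    if profile is not None:
        profile.l0 = l0
        profile.fit_residual = resid
        profile.fit_range = (float(x.min()), float(x.max()))
    return l0


# ---------------------------------------------------------------------------
# numerical correlation from simulated systems

def _steady_with_factor(system: ReactionSystem, node, factor: float,
                        guess: SystemState) -> SystemState:
    return steady_state(perturb_generation_rate(system, node, factor), state0=guess)


def correlation_function_numerical(system: ReactionSystem, source,
                                   delta_fraction: float = 0.01,
                                   max_distance: int | None = None,
                                   base_state: SystemState | None = None) -> CorrelationProfile:
    """Correlation profile from an actual generation-rate perturbation.

    Finds (by 1-D root solve) the reduction of the source's generation rate
    for which the source level drops by exactly ``delta_fraction``, relaxes
    the system to the new steady state and returns

        C(ell) = (Delta L_ell / L_ell) / (Delta L_0 / L_0)

    over same-side nodes at even bipartite distance ell from the source
    (targets when the source is a target, miRNAs when it is a miRNA).
    """
    if not 0.0 < delta_fraction < 0.5:
        raise ValueError("delta_fraction must be in (0, 0.5): linear-response regime")
    ss0 = base_state if base_state is not None else steady_state(system)
    L0 = ss0.level(system, source)
    if L0 <= 0:
        raise ValueError(f"source {source!r} has zero steady-state level")

    def gap(factor: float) -> float:
        ss = _steady_with_factor(system, source, factor, ss0)
        return (L0 - ss.level(system, source)) / L0 - delta_fraction

    lo = max(1.0 - 20.0 * delta_fraction, 1e-6)
    while gap(lo) < 0 and lo > 1e-6:
        lo = max(lo * 0.5, 1e-6)
    factor = brentq(gap, lo, 1.0, xtol=1e-12)
    ss1 = _steady_with_factor(system, source, factor, ss0)

    # same-side responders grouped by even bipartite distance
    G = nx.Graph(system.topology.edges)
    G.add_nodes_from(system.topology.mirnas + system.topology.mrnas)
    dist = nx.single_source_shortest_path_length(G, source)
    src_kind, _ = system.node_index(source)
    side = system.topology.mirnas if src_kind == "R" else system.topology.mrnas
    denom = (L0 - ss1.level(system, source)) / L0
    by_dist: dict[int, list[float]] = {}
    for node in side:
        if node not in dist:
            continue
        d = dist[node]
        if max_distance is not None and d > max_distance:
            continue
        l_old, l_new = ss0.level(system, node), ss1.level(system, node)
        if l_old <= 0:
            continue
        by_dist.setdefault(d, []).append(((l_old - l_new) / l_old) / denom)
    ds = np.array(sorted(by_dist), dtype=float)
    vals = np.array([np.mean(by_dist[int(d)]) for d in ds])
    profile = CorrelationProfile(source=source, distances=ds, values=vals,
                                 delta_fraction=delta_fraction)
    try:
        fit_correlation_length(profile)
    except ValueError:
        pass  # too few decaying points; l0 stays NaN
    return profile


def parameter_sweep(base: KineticParams, parameter: str, grid,
                    mode: str = "analytic",
                    chain_N: int = 50, delta_fraction: float = 0.01,
                    max_distance: int = 16) -> SweepResult:
    """Correlation length across a grid of one kinetic parameter.

    ``parameter`` is a KineticParams field name, or ``'g'`` (sweeping g_R
    and g_T together) or ``'delta_g'`` (g_R held at base, g_T = g_R -
    delta_g).  ``mode``: 'analytic', 'numerical' (circular-chain fit) or
    'both'.  Grid points outside the qp < 1/4 validity domain are flagged
    with NaN and the sweep continues.
    """
    from .kinetics import build_chain  # local import to avoid cycle at module load

    if mode not in ("analytic", "numerical", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = np.asarray(list(grid), dtype=float)
    l0_a = np.full(grid.shape, np.nan)
    l0_f = np.full(grid.shape, np.nan)
    delta_g = None
    if parameter == "delta_g":
        delta_g = grid.copy()
    for k, val in enumerate(grid):
        if parameter == "g":
            p = base.replace(g_R=val, g_T=val)
        elif parameter == "delta_g":
            p = base.replace(g_T=base.g_R - val)
        else:
            p = base.replace(**{parameter: val})
        if mode in ("analytic", "both"):
            try:
                l0_a[k], _ = correlation_length_closed_form(p)
            except ValueError:
                warnings.warn(f"{parameter}={val}: qp >= 1/4, analytic point flagged")
        if mode in ("numerical", "both"):
            chain = build_chain(chain_N, p, boundary="circular")
            prof = correlation_function_numerical(
                chain, "T0", delta_fraction=delta_fraction, max_distance=max_distance)
            l0_f[k] = prof.l0
    return SweepResult(parameter=parameter, grid=grid,
                       l0_analytic=l0_a, l0_fitted=l0_f, delta_g=delta_g)


def network_correlation_matrix(system: ReactionSystem, sources=None,
                               factor: float = 0.9) -> pd.DataFrame:
    """Per-pair correlation values on a bipartite network, grouped by distance.

    For each source (default: all miRNAs) the source's generation rate is
    multiplied by ``factor``, the system re-relaxed, and the correlation
    value (Delta L_j/L_j)/(Delta L_src/L_src) recorded for every same-side
    node j.  Returns a tidy frame (source, responder, distance, value);
    responders disconnected from their source get distance NaN and are
    flagged unreachable.
    """
    if sources is None:
        sources = list(system.topology.mirnas)
    ss0 = steady_state(system)
    G = nx.Graph(system.topology.edges)
    G.add_nodes_from(system.topology.mirnas + system.topology.mrnas)
    rows = []
    for src in sources:
        kind, _ = system.node_index(src)
        side = system.topology.mirnas if kind == "R" else system.topology.mrnas
        ss1 = _steady_with_factor(system, src, factor, ss0)
        L0_old, L0_new = ss0.level(system, src), ss1.level(system, src)
        denom = (L0_old - L0_new) / L0_old
        dist = nx.single_source_shortest_path_length(G, src)
        for node in side:
            l_old, l_new = ss0.level(system, node), ss1.level(system, node)
            value = (((l_old - l_new) / l_old) / denom) if l_old > 0 else np.nan
            rows.append((src, node, float(dist.get(node, np.nan)), value,
                         node not in dist))
    return pd.DataFrame(rows, columns=["source", "responder", "distance",
                                       "value", "unreachable"])


def mean_correlation_by_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean correlation per (source, distance), unreachable pairs excluded."""
    ok = matrix[~matrix["unreachable"]]
    return (ok.groupby(["source", "distance"])["value"]
            .agg(["mean", "count"]).reset_index())
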