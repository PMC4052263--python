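"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: Gaussian ensembles
of kinetic parameters (for averaging correlation profiles over chain
instantiations), heavy-tailed bipartite interactomes in the CLASH table
dialect (so the confidence filters and graph statistics are exercisable),
and simulated miRNA-depletion experiments in which per-gene log2 fold
changes are produced by the mass-action model itself plus measurement
noise, together with the true distance classification for recovery tests.

All generators are deterministic under a fixed seed (sorted, integer-coded
identifiers; a single numpy Generator per call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import build_bipartite
from .kinetics import (
    BipartiteTopology,
    KineticParams,
    build_network,
    perturb_generation_rate,
    steady_state,
)
from .sep_analysis import SepClassification, classify_sep_groups

__all__ = [
    "GeneratorConfig",
    "sample_parameters",
    "generate_interactome",
    "fig2_like_subnetwork",
    "simulate_perturbation_experiment",
]

_PARAM_FIELDS = ("g_R", "g_T", "b", "u_C", "d_R", "d_T", "d_C", "alpha")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic pipeline.

    Defaults: a chain long enough for the probed window to sit far from
    the boundaries; parameter scatter of 10% (coefficient of variation)
    around the base rates; an interactome of 50 miRNAs x 400 genes with
    mean gene degree 2.5 and tail exponent 2.6; depletion of the hub
    miRNA to 20% of its generation rate; measurement noise of 0.1 log2
    units; twice as many unregulated control genes as interactome genes
    so median normalization stays anchored on unperturbed genes.
    """

    seed: int = 0
    chain_N: int = 50
    base_params: KineticParams = field(default_factory=KineticParams)
    cv: float = 0.1
    n_mirna: int = 50
    n_mrna: int = 400
    mean_degree: float = 2.5
    exponent: float = 2.6
    source: str | None = None  # None: highest-degree miRNA
    depletion_factor: float = 0.2
    noise_sd: float = 0.1
    n_control: int = 800

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if min(self.n_mirna, self.n_mrna, self.chain_N) < 1:
            raise ValueError("sizes must be >= 1")


def sample_parameters(base: KineticParams, cv: float = 0.1, n: int = 1,
                      seed: int | None = None) -> list[KineticParams]:
    """n kinetic-parameter sets with per-parameter independent Gaussians.

    Each rate is drawn with mean equal to its base value and standard
    deviation cv * value; negative draws are rejected and resampled;
    alpha is clipped into [0, 1].
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kwargs = {}
        for name in _PARAM_FIELDS:
            mu = getattr(base, name)
            if cv == 0.0 or mu == 0.0:
                kwargs[name] = mu
                continue
            val, tries = -1.0, 0
            while val < 0:
                val = rng.normal(mu, cv * abs(mu))
                tries += 1
                if tries > 1000:
                    raise ValueError(
                        f"rejection rate too high sampling {name} (cv={cv})")
            kwargs[name] = min(val, 1.0) if name == "alpha" else val
        out.append(KineticParams(**kwargs))
    return out


def generate_interactome(n_mirna: int, n_mrna: int, mean_degree: float = 2.5,
                         exponent: float = 2.6, seed: int | None = None) -> pd.DataFrame:
    """Synthetic CLASH-style interaction table with heavy-tailed degrees.

    Gene degrees are rounded Pareto draws with tail exponent ``exponent``
    and the minimum calibrated so the mean is ``mean_degree``; each
    interaction's miRNA endpoint is drawn proportionally to Pareto node
    weights, producing hub miRNAs.  Duplicate pairs are dropped.  Binding
    free energies are Normal(-17, 3) kcal/mol and read counts geometric,
    so confidence filtering has realistic effect.

    Returns a canonical table (mirna, gene, reads, energy), sorted.
    """
    if min(n_mirna, n_mrna) < 1:
        raise ValueError("sizes must be >= 1")
    if exponent <= 2.0:
        raise ValueError("tail exponent must exceed 2 for a finite mean degree")
    rng = np.random.default_rng(seed)
    a = exponent - 1.0  # Pareto shape of the continuous envelope

    def mean_rounded(kmin: float) -> float:
        # E[max(1, round(kmin * U^(-1/a)))] by quadrature on the quantile
        u = (np.arange(200000) + 0.5) / 200000
        return float(np.mean(np.maximum(1, np.round(kmin * (1 - u) ** (-1 / a)))))

    # calibrate the Pareto scale so the realized mean degree hits the request
    lo, hi = 1e-3, mean_degree
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_rounded(mid) < mean_degree:
            lo = mid
        else:
            hi = mid
    kmin = 0.5 * (lo + hi)
    degrees = np.maximum(1, np.round(
        kmin * (1.0 - rng.random(n_mrna)) ** (-1.0 / a)).astype(int))
    degrees = np.minimum(degrees, n_mirna)  # a gene cannot exceed one edge per miRNA
    weights = (1.0 - rng.random(n_mirna)) ** (-1.0 / a)
    weights /= weights.sum()
    mirna_ids = [f"MIR{i:04d}" for i in range(n_mirna)]
    gene_ids = [f"G{j:05d}" for j in range(n_mrna)]
    pairs = set()
    for j, k in enumerate(degrees):
        chosen = rng.choice(n_mirna, size=int(k), replace=False, p=weights)
        for i in sorted(chosen):
            pairs.add((mirna_ids[i], gene_ids[j]))
    pairs = sorted(pairs)
    energies = np.round(rng.normal(-17.0, 3.0, size=len(pairs)), 2)
    reads = rng.geometric(0.25, size=len(pairs))
    return pd.DataFrame({
        "mirna": [p[0] for p in pairs],
        "gene": [p[1] for p in pairs],
        "reads": reads.astype(int),
        "energy": energies,
    })


def fig2_like_subnetwork() -> BipartiteTopology:
    """Synthetic stand-in for the dense 15-miRNA / 6-mRNA subnetwork used in
    the network perturbation experiments.

    The published subnetwork exists only as a figure, so this constructs a
    synthetic topology with the same side sizes: a backbone of 6 genes
    chained by 5 bridging miRNAs (each regulating two adjacent genes) plus
    10 leaf miRNAs regulating a single gene, giving paths up to 6-sep
    between miRNAs.
    """
    genes = tuple(f"m{i}" for i in range(1, 7))
    bridges = [(f"b{i}", (f"m{i}", f"m{i + 1}")) for i in range(1, 6)]
    leaf_counts = {"m1": 2, "m2": 2, "m3": 2, "m4": 2, "m5": 1, "m6": 1}
    leaves = []
    for g, cnt in leaf_counts.items():
        for k in range(1, cnt + 1):
            leaves.append((f"L{g[1:]}_{k}", (g,)))
    mirnas = tuple(name for name, _ in bridges) + tuple(name for name, _ in leaves)
    edges = []
    for name, targets in bridges + leaves:
        for t in targets:
            edges.append((name, t))
    return BipartiteTopology(mirnas, genes, tuple(edges))


def simulate_perturbation_experiment(
        interactome: pd.DataFrame | BipartiteTopology,
        params: KineticParams | None = None,
        source: str | None = None,
        depletion_factor: float = 0.2,
        noise_sd: float = 0.1,
        seed: int | None = None,
        n_control: int = 800,
        generation_mode: str = "degree_proportional",
        depletion_mode: str = "generation",
) -> tuple[pd.DataFrame, SepClassification]:
    """Simulate a miRNA-depletion experiment on an interactome.

    Builds the mass-action system on the connected component containing
    the source miRNA, computes steady states before and after reducing the
    source's activity, and emits per-gene log2(T_after/T_before) plus
    Gaussian measurement noise, together with ``n_control`` extra genes
    carrying pure noise (the array genes outside the interactome).  The
    returned classification is the ground-truth distance stratification.

    ``depletion_mode='generation'`` multiplies the source's generation
    rate by ``depletion_factor``;  ``'decoy'`` instead adds a synthetic
    high-affinity decoy target (the anti-miR oligonucleotide) whose
    generation rate is (1 - depletion_factor) times the source's, which
    titrates the miRNA away from its endogenous targets.
    """
    params = params if params is not None else KineticParams()
    topo = interactome if isinstance(interactome, BipartiteTopology) \
        else build_bipartite(interactome)
    deg = {m: 0 for m in topo.mirnas}
    for r, _ in topo.edges:
        deg[r] += 1
    if source is None:
        source = max(sorted(deg), key=lambda m: deg[m])
    if source not in topo.mirnas:
        raise KeyError(f"source {source!r} not an interactome miRNA")
    # connected component of the source
    adj: dict = {}
    for r, t in topo.edges:
        adj.setdefault(r, set()).add(t)
        adj.setdefault(t, set()).add(r)
    comp, frontier = {source}, {source}
    while frontier:
        frontier = set().union(*(adj.get(n, set()) for n in frontier)) - comp
        comp |= frontier
    sub_edges = tuple(e for e in topo.edges if e[0] in comp)
    sub = BipartiteTopology(
        tuple(m for m in topo.mirnas if m in comp),
        tuple(t for t in topo.mrnas if t in comp),
        sub_edges)

    if depletion_mode == "generation":
        system = build_network(sub, params, generation_mode=generation_mode)
        perturbed = perturb_generation_rate(system, source, depletion_factor)
    elif depletion_mode == "decoy":
        decoy = "DECOY"
        sub_d = BipartiteTopology(sub.mirnas, sub.mrnas + (decoy,),
                                  sub.edges + ((source, decoy),))
        system0 = build_network(sub_d, params, generation_mode=generation_mode)
        kind, di = system0.node_index(decoy)
        system0.g_T[di] = 0.0  # decoy absent before transfection
        system = system0
        perturbed = system0.copy()
        _, di = perturbed.node_index(decoy)
        skind, si = perturbed.node_index(source)
        perturbed.g_T[di] = (1.0 - depletion_factor) * perturbed.g_R[si]
    else:
        raise ValueError(f"unknown depletion_mode {depletion_mode!r}")

    try:
        ss0 = steady_state(system)
        ss1 = steady_state(perturbed, state0=ss0)
    except RuntimeError as err:
        raise RuntimeError(
            f"simulation did not converge on the {len(comp)}-node subsystem") from err

    rng = np.random.default_rng(seed)
    genes = [t for t in sub.mrnas if t != "DECOY"]
    before = np.array([ss0.level(system, g) for g in genes])
    after = np.array([ss1.level(perturbed, g) for g in genes])
    log2fc = np.log2(after / before)
    if noise_sd > 0:
        log2fc = log2fc + rng.normal(0.0, noise_sd, size=len(genes))
    controls = [f"CTRL{k:05d}" for k in range(n_control)]
    ctrl_fc = rng.normal(0.0, noise_sd, size=n_control) if noise_sd > 0 \
        else np.zeros(n_control)
    expr = pd.DataFrame({
        "gene": genes + controls,
        "log2fc": np.concatenate([log2fc, ctrl_fc]),
    })
    universe = genes + controls
    classification = classify_sep_groups(sub, source, universe=universe)
    return expr, classification
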