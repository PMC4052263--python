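# Methods

## Model

`cernet` models post-transcriptional cross-talk between RNAs that never
touch each other directly.  A miRNA R and a target RNA T bind by
mass-action kinetics into a complex C; the complex either unbinds (rate
`u_C`) or is degraded (rate `d_C`).  A fraction `alpha` of the
complex-degradation events also consumes the miRNA — the *stoichiometric
factor*, interpolating between the catalytic regime (`alpha = 0`, the
miRNA is recycled) and the fully stoichiometric regime (`alpha = 1`).
For a single pair:

    dR/dt = g_R - b·R·T + u_C·C + (1 - alpha)·d_C·C - d_R·R
    dT/dt = g_T - b·R·T + u_C·C - d_T·T
    dC/dt = b·R·T - (u_C + d_C)·C

Because binding removes both species, a change in either free level feeds
back on the other: the network of miRNA-target interactions is effectively
*undirected*, and a perturbation of one node can travel along alternating
paths of co-regulated targets and target-sharing miRNAs ("distant
ceRNAs").  The package assembles these equations for a single pair, for a
chain of 2N alternating species (targets at even positions, miRNAs at odd
positions), and for an arbitrary bipartite interaction network with one
complex species per edge.

All levels are dimensionless; rates are per second, the binding rate per
(level·second).

### Fixed points

Two closed forms anchor everything numerical:

* **Pair**: eliminating C gives `T = g_T/(d_T + bt·R)` and
  `R = g_R/(d_R + alpha·bt·T)` with the effective binding rate
  `bt = b·d_C/(u_C + d_C)`; substituting one into the other leaves a
  single quadratic whose nonnegative root is the unique physical fixed
  point.
* **Homogeneous circular chain** (every miRNA flanked by two targets and
  vice versa): the same elimination with a factor 2 on the binding terms.
  The root is implemented in its conjugate form
  `T = 2·g_T·d_R / (A + sqrt(A² + 8·alpha·bt·g_T·d_R·d_T))` with
  `A = 2·bt·(g_R - alpha·g_T) + d_R·d_T`, which is algebraically identical
  to the textbook quadratic root but cancellation-free, so the catalytic
  limit `alpha -> 0` needs no special branch.

Both closed forms are verified in the tests by two independent routes:
the residual of the full ODE right-hand side at the closed-form state
(< 1e-9 relative), and agreement with the Newton/relaxation solver
started far away (< 1e-6 relative).

### Correlation function and correlation length

The propagation strength is quantified by the correlation function

    C(ell) = (ΔT_ell / T_ell) / (ΔT_0 / T_0),

the normalized steady-state response of the target at even chain distance
`ell` to a small sustained perturbation of the source target.  On the
homogeneous chain, linearizing around the fixed point gives the recurrence

    C(0) = 1,  C(ell) = qp·[C(ell+2) + 2·C(ell) + C(ell-2)],  ell >= 2,

with `p = -alpha·bt·g_R/(d_R + 2·alpha·bt·T)²` and
`q = -bt·g_T/(d_T + 2·bt·R)²` evaluated at the chain fixed point.  Its
decaying solution is a pure exponential `C(ell) = exp(-ell/l0)` with

    l0 = 1 / arcosh( 1 / (2·sqrt(qp)) ).

Substituting the exponential into the recurrence gives
`1 = 4·qp·cosh²(1/l0)`, which also yields the validity condition
`qp < 1/4`.  In fact `qp < 1/4` holds for *every* valid parameter set:
rewriting with the fixed-point identities,
`qp = [alpha·bt·T/(d_R + 2·alpha·bt·T)] · [bt·R/(d_T + 2·bt·R)]`, and each
bracket is strictly below 1/2 whenever `d_R, d_T > 0`.  The domain guards
on the raw-`qp` entry points are therefore defensive only.

For equal generation rates (`g_R = g_T = g`) the whole dependence
collapses onto `X = bt·g/(d_R·d_T)` and `alpha`:

    1/sqrt(qp) = [1 + 2X(1+alpha) + sqrt((2X(1-alpha)+1)² + 8·alpha·X)]
                 / (2·sqrt(alpha)·X).

This expression was derived symbolically (sympy) from the chain fixed
point and the `p`, `q` definitions; the `sqrt(alpha)` prefactor is
enforced by a two-route consistency test against `p·q` computed from raw
rates.  At `alpha = 1, X = 1` it gives the hand-checkable value
`qp = 1/16`, `l0 = 1/arcosh(2) ≈ 0.7593`.

Three independent routes to `l0` are kept deliberately separate and
compared in the acceptance suite:

1. the closed form above;
2. a brute-force linear solve of the truncated recurrence with a far
   absorbing boundary (the oracle — no exponential ansatz involved);
3. a least-squares fit of `log C(ell)` versus `ell` on profiles obtained
   by actually perturbing a simulated chain and re-relaxing it.

Route 3 implements the operational definition: a 1-D root solve finds the
generation-rate reduction that lowers the source level by exactly
`delta_fraction` (default 1%, checked to be in the linear regime by a
halving test), the system is relaxed to its new steady state, and the
level shifts of all same-side nodes are recorded by even bipartite
distance.  Fits exclude points below 1e-10 (floating-point floor) and
need at least three usable points.

On networks the same machinery produces per-pair correlation matrices:
each source miRNA is depleted to 9/10 of its generation rate and the
response of every same-side node is normalized by the source's own
response, then grouped by bipartite distance (2-sep, 4-sep, ...).

### Response times

The response time of a node is the first time its level crosses halfway
between its old and new steady states (linear interpolation between
integration samples), reported relative to the source's own response
time.  The ordered-propagation property (relative response time
non-decreasing with distance) is asserted in the 9/10-knockdown linear
regime; under strong knockdowns (factor 0.5) the first miRNA's *relative*
time can slightly exceed the next target's because the responses are no
longer small — a nonlinear effect, documented here and excluded from the
monotonicity claim.

## Default parameters

The defaults (`KineticParams()`) are
`g_R = g_T = 1`, `d_R = d_T = 0.1`, `b = 0.525`, `u_C = 0.05`,
`d_C = 0.1`, `alpha = 1`, giving `bt = 0.35`, `X = 35`, `qp ≈ 0.197`
and an analytic correlation length `l0 ≈ 2.01` — a regime in which a
perturbation measurably reaches 4-6 edges, the interesting regime for
distant cross-talk, while degradation (turnover time 10 s) still
dominates the long-time scale.  Generation and degradation set the level
scale near 1 so absolute and relative tolerances behave uniformly in the
sweeps, which span roughly a decade around each default.

Steady states are declared at `max |rhs| < 1e-10 + 1e-8·level`
componentwise (mixed criterion because sweeps span decades of level
scale); the solver is a damped Newton (`scipy.optimize.root`, hybr, with
the analytic Jacobian) with an LSODA relaxation fallback and a
nonnegativity check.

## Interactome statistics

CLASH-style tables are read with a configurable column dialect (a bundled
dialect matches the Helwak-layout supplementary tables); transcript rows
of the same gene are aggregated by summing reads and keeping the minimum
(most stable) binding free energy per miRNA-gene pair — the energy rule is
our choice, recorded here, since the combination rule is not standard.
High-confidence filtering keeps energies strictly below -13.4 kcal/mol;
an optional `reads > n` filter is off by default.

Graph statistics follow the usual conventions: ASPL is the mean shortest
path over connected ordered node pairs of the largest component;
clustering is the unweighted local coefficient averaged over all nodes
(degree < 2 contributes 0); the small-world coefficient
`sigma = (C/C_rand)/(ASPL/ASPL_rand)` uses an ensemble of 100 seeded
Erdős–Rényi graphs with matched node count and edge probability
`p = |E|/C(|V|,2)`, degenerate draws resampled and counted.  Projections
are simple weighted graphs (shared-neighbour counts, no self-loops).  The
degree-distribution fit offers two modes: log-log least squares on the
frequency support (slope magnitude and |Pearson r|), which is the
conventional quick diagnostic but biased low when tail bins are sparse,
and a zeta-normalized discrete maximum likelihood with selectable `k_min`,
which is the estimator of choice for recovery tests.

## k-sep classification and group comparison

An artificial source node is attached to the perturbed miRNA, so the
miRNA is 1-sep, its targets 2-sep, miRNAs sharing those targets 3-sep,
and so on; labels are minimum BFS distances, odd for miRNAs and even for
genes.  To keep the distance groups clean, a gene at distance 2k is
*retained* in the 2k-sep group only if every miRNA regulating it is
(2k-1)-sep; genes with mixed-label regulator sets are excluded (their
response would mix path lengths).  The number of defining-group
regulators is recorded per retained gene for the single- versus
multi-regulator subgroup analysis.  Control genes are array genes absent
from the interactome altogether.  Classification defaults to the full
interaction table (including low-confidence records) so that borderline
direct targets are not misread as distant responders; a threshold switch
reruns on high-confidence records only.

Expression tables are median-centred (global median log2 fold change to
0), then groups are compared with two-sided two-sample Kolmogorov–Smirnov
tests: exact small-sample p-values when both groups have n ≤ 25,
asymptotic otherwise; no multiple-testing correction is applied and all
performed tests are reported.  The TF-confound filter removes from the
4-sep group any listed target of a transcription-factor activator whose
transcript is 2-sep, plus (one co-regulation step by default,
configurable depth) genes sharing a miRNA regulator with such a target.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline needs:

* **Parameter ensembles** — per-parameter independent Gaussians, mean at
  the base value, sd = cv × value (default cv = 0.1), negative draws
  resampled, `alpha` clipped to [0, 1].
* **Interactomes** — gene degrees are rounded Pareto draws with tail
  exponent 2.6 and the scale calibrated by quadrature so the realized
  mean degree matches the request (default 2.5); each interaction's miRNA
  endpoint is drawn in proportion to Pareto node weights, producing hub
  miRNAs.  Binding energies ~ Normal(-17, 3) kcal/mol and geometric read
  counts make the confidence filters do real work.  Defaults: 50 miRNAs ×
  400 genes.
* **Depletion experiments** — the mass-action system is built on the
  connected component of the source miRNA with degree-proportional
  generation rates (a hub miRNA must be abundant in proportion to its
  target load, or its free level is titrated to zero and no signal can
  propagate); steady states are computed before and after multiplying the
  source's generation rate by the depletion factor (default 0.2), and
  per-gene log2(T_after/T_before) is emitted with additive Gaussian noise
  (default sd 0.1 log2 units) plus 800 pure-noise control genes — twice
  the interactome gene count, so median normalization stays anchored on
  unperturbed genes, as in a genome-scale array where non-targets
  dominate.  An alternative `decoy` mode models the anti-miR
  oligonucleotide explicitly as a new high-affinity target species
  instead of reducing generation.

Under these defaults the simulated experiment produces 2-sep median
shifts of ~3.5 log2 units — larger than typical microarray observations,
because the default kinetics are strongly coupled and fully
stoichiometric and the synthetic interactome is small and dense.  What
the passing tests demonstrate is therefore the *pipeline's recovery
property* (ordering of group medians, K-S separation from controls, the
multi-regulator enhancement) under a known ground truth, not the effect
sizes of any real cell line.  Real data differ in ways the generator does
not emulate: probe-level microarray noise structure, expression-dependent
variance, transcriptional (TF) confounding, AGO availability, and an
interactome that samples only part of the true network.

## Numerical choices

* ODE integration: LSODA with analytic dense Jacobian, rtol 1e-9 /
  atol 1e-12; negative excursions beyond 1e-8 abort, smaller ones are
  clipped to zero.
* Steady-state Newton polish tolerance xtol 1e-13; independence from the
  initial condition is tested from two distant starts (agreement 1e-6).
* Root solve for the prescribed source perturbation: Brent on the
  generation-rate factor, xtol 1e-12, bracket widened geometrically if
  the initial guess does not straddle.
* Recurrence oracle: banded tridiagonal solve; the far boundary is placed
  at least 40 correlation lengths beyond the requested range so
  truncation error is below the fit floor.
* Ties and degenerate inputs: duplicate interaction records collapse to
  one edge; a chain of N = 1 pairs degenerates exactly to the pair model;
  `b = 0` or `bt = 0` short-circuit to the decoupled g/d fixed point.

## Problem sizes

The test and acceptance runs use a 100-pair circular chain for the
correlation triangle, a 26-pair open chain for response times (probe
window of 11 positions at the centre, well away from the boundaries), the
15 × 6 subnetwork for the dense-network experiments, a 50 × 400
interactome (~1000 edges, ~1450 state variables) for the end-to-end
recovery, and 50 chain instantiations of 30 heterogeneous pairs for the
ensemble-averaged correlation fit.  These sizes keep every stage
comfortably within a single-CPU desk-scale run while leaving all
qualitative regimes (propagation over ≥ 6 edges, hub-dominated degree
distributions, group sizes in the hundreds) intact.

## Known limitations

* The dense 15 × 6 subnetwork is a synthetic stand-in with the published
  side sizes and a backbone-plus-leaves topology; the original subnetwork
  exists only as a figure.
* The chain theory assumes homogeneous parameters; on heterogeneous
  ensembles the fitted `l0` of the *averaged* profile (≈ 1.8 under 10%
  scatter) sits slightly below the homogeneous closed form (≈ 2.0), as
  averaging exponentials weights short-`l0` instances more at large
  distances.
* Stochastic (Gillespie) dynamics, translation-level readouts, AGO as a
  dynamic species, and delay terms are out of scope; levels are
  deterministic means.
* `sigma` depends on the ER null and is noisy for small graphs; the
  ensemble size (default 100) and seed are explicit everywhere.
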