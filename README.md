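# cernet

Perturbation propagation between **distant ceRNAs** in miRNA-target
networks: mass-action kinetics, correlation-length theory, bipartite
interactome statistics, and distance-stratified expression analysis.

## The problem

miRNAs repress their target RNAs by binding them into complexes, and the
binding removes both partners from the free pool.  The regulation is
therefore bidirectional: knocking down one target frees its miRNA
regulators, which then repress their *other* targets more strongly; a
miRNA depletion, conversely, de-represses its targets, which titrate
*other* miRNAs away from theirs.  A perturbation can thus travel along
alternating paths of co-regulated targets and target-sharing miRNAs —
RNAs that share no regulator at all can still influence each other as
*distant ceRNAs* (competing endogenous RNAs).  This package implements
the quantitative machinery for that picture, for modellers and for
analysts of perturbation expression data:

* **`cernet.kinetics`** — the mass-action ODE system for a miRNA-target
  pair, for a chain of 2N alternating species, and for arbitrary
  bipartite networks; closed-form fixed points, integration, steady-state
  solving, perturbations and response times.
* **`cernet.correlation`** — the correlation function
  `C(ell) = (ΔT_ell/T_ell)/(ΔT_0/T_0)` and the correlation length
  `l0 = 1/arcosh(1/(2√(qp)))` with
  `qp = [α·b̃·T/(d_R+2α·b̃·T)]·[b̃·R/(d_T+2b̃·R)]`, by closed form, by a
  brute-force recurrence solve, and by exponential fits to simulated
  perturbations; parameter sweeps and network correlation matrices.
* **`cernet.interactome`** — CLASH-style interaction tables (dialect
  configurable), the −13.4 kcal/mol confidence filter, bipartite graphs
  and their weighted projections, ASPL, clustering, small-world
  coefficient σ against an Erdős–Rényi ensemble, degree power-law fits.
* **`cernet.sep_analysis`** — stratification of genes by bipartite
  distance from a perturbed miRNA (2-sep, 4-sep, 6-sep groups with the
  regulator-uniqueness retention rule), median normalization of log2
  fold changes, two-sided Kolmogorov–Smirnov group comparisons, and a
  transcription-factor confound filter.
* **`cernet.synth`** — generators for everything above: kinetic-parameter
  ensembles, heavy-tailed synthetic interactomes, and simulated
  depletion experiments with known ground truth.
* **`cernet.cli`** — a `cernet` console script
  (`simulate-chain | correlation-sweep | network-stats | classify-sep |
  perturb-analyze | synth`) that writes artifacts plus a JSON run
  manifest.

The scientific background and every numerical convention are documented
in [docs/methods.md](docs/methods.md).  The `analysis/` directory holds
numbered driver scripts that reproduce the package's main analyses and
write tables under `results/`.

## Worked example

Theory versus simulation for the correlation length on a homogeneous
chain, then a simulated miRNA-depletion experiment pushed through the
k-sep pipeline:

```python
import numpy as np
import cernet as cn

params = cn.KineticParams()          # b̃=0.35, X=35, α=1
l0, dp = cn.correlation_length_closed_form(params)
chain = cn.build_chain(100, params, boundary="circular")
prof = cn.correlation_function_numerical(chain, "T0", delta_fraction=0.01,
                                         max_distance=20)
print(f"qp = {dp.qp:.4f}, l0 analytic = {l0:.4f}, l0 fitted = {prof.l0:.4f}")

cfg = cn.GeneratorConfig(seed=1)
tab = cn.generate_interactome(cfg.n_mirna, cfg.n_mrna, cfg.mean_degree,
                              cfg.exponent, seed=cfg.seed)
expr, cls = cn.simulate_perturbation_experiment(
    tab, cfg.base_params, depletion_factor=cfg.depletion_factor,
    noise_sd=cfg.noise_sd, n_control=cfg.n_control, seed=cfg.seed)
norm = cn.normalize_log2fc(expr)
for g in ("2-sep", "4-sep", "control"):
    vals = norm.loc[norm.gene.isin(set(cls.group(g))), "log2fc"]
    print(f"median log2FC {g}: {vals.median():+.3f} (n={len(vals)})")
comp = cn.compare_groups(norm, cls, [("2-sep", "control")])[0]
print(f"K-S 2-sep vs control: D = {comp.statistic:.3f}, p = {comp.pvalue:.3g}")
```

Output:

```
qp = 0.1969, l0 analytic = 2.0058, l0 fitted = 2.0063
median log2FC 2-sep: +3.533 (n=29)
median log2FC 4-sep: +1.649 (n=283)
median log2FC control: -0.073 (n=800)
K-S 2-sep vs control: D = 1.000, p = 0
```

The analytic correlation length and the fit to the actually simulated
chain agree to 0.03%.  In the simulated experiment the depleted hub
miRNA's direct targets (2-sep) rise strongly; genes two further edges
away (4-sep) — none of which the source regulates — rise by less, and
unregulated control genes stay at the normalization baseline: the
distance-ordered signature of distant-ceRNA cross-talk, recovered from
noisy expression values by the classification pipeline.

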