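#!/usr/bin/env python
"""Correlation-length theory versus simulation.

Computes the correlation function C(ell) three independent ways on the
homogeneous circular chain — the analytic closed form, the truncated
recurrence solved as a linear system, and an exponential fit to an actual
perturb-and-relax simulation — then sweeps every kinetic parameter to map
the direction of its effect on the correlation length, including the
generation-rate gap delta_g = g_R - g_T.  Writes sweep tables to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import cernet as cn

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

base = cn.KineticParams()
l0_closed, dp = cn.correlation_length_closed_form(base)
C = cn.recurrence_solve(dp.qp, 20)
l0_rec = cn.fit_correlation_length(distances=np.arange(0, 22, 2), values=C)
chain = cn.build_chain(100, base, boundary="circular")
prof = cn.correlation_function_numerical(chain, "T0", 0.01, max_distance=20)
prof.to_frame().to_csv(OUT / "correlation_profile_chain.tsv", sep="\t", index=False)

print(f"correlation length, three routes (default chain, qp = {dp.qp:.4f}):")
print(f"  closed form      l0 = {l0_closed:.4f}")
print(f"  recurrence solve l0 = {l0_rec:.4f}")
print(f"  simulated fit    l0 = {prof.l0:.4f}")

sweeps = [
    ("b", np.linspace(0.1, 0.9, 7)),
    ("g", np.linspace(0.4, 2.0, 7)),
    ("alpha", np.linspace(0.1, 1.0, 7)),
    ("d_R", np.linspace(0.05, 0.4, 7)),
    ("d_T", np.linspace(0.05, 0.4, 7)),
    ("u_C", np.linspace(0.0, 0.3, 7)),
    ("delta_g", np.linspace(0.0, 0.4, 7)),
]
frames = []
for name, grid in sweeps:
    res = cn.parameter_sweep(base, name, grid, mode="analytic")
    frames.append(res.to_frame())
    sign = "+" if res.l0_analytic[-1] > res.l0_analytic[0] else "-"
    print(f"  l0 vs {name:8s}: monotone ({sign})  "
          f"[{res.l0_analytic[0]:.3f} .. {res.l0_analytic[-1]:.3f}]")
pd.concat(frames, ignore_index=True).to_csv(OUT / "correlation_sweeps.tsv",
                                            sep="\t", index=False)
print(f"wrote {OUT / 'correlation_profile_chain.tsv'} and {OUT / 'correlation_sweeps.tsv'}")
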