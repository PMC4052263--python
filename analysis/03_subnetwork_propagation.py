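#!/usr/bin/env python
"""Perturbation propagation on a dense interactome subnetwork.

Depletes each of the 15 miRNAs of the synthetic 15x6 subnetwork to 9/10 of
its generation rate in turn (degree-proportional generation rates) and
records the correlation value for every other miRNA, grouped by bipartite
distance.  The average response attenuates from 2-sep to 4-sep for every
source, while individual responders can sit far above the group mean.
Writes the full 15x15 correlation matrix to results/.
"""

from pathlib import Path

import cernet as cn
from cernet.correlation import mean_correlation_by_distance

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

system = cn.build_network(cn.fig2_like_subnetwork(), cn.KineticParams(),
                          generation_mode="degree_proportional")
mat = cn.network_correlation_matrix(system, factor=0.9)
mat.to_csv(OUT / "subnetwork_correlations.tsv", sep="\t", index=False)

means = mean_correlation_by_distance(mat)
pivot = means.pivot(index="source", columns="distance", values="mean")
grand2, grand4 = pivot[2.0].mean(), pivot[4.0].mean()
n_atten = int((pivot[2.0] > pivot[4.0]).sum())
print(f"15 perturbation experiments (9/10 depletion), {len(mat)} correlation values")
print(f"  grand mean correlation: 2-sep {grand2:.3f}, 4-sep {grand4:.3f}")
print(f"  2-sep mean exceeds 4-sep mean for {n_atten}/15 sources")

grouped = mat[(mat.distance > 0) & ~mat.unreachable]
for d in (2.0, 4.0):
    g = grouped[grouped.distance == d]
    hot = g[g.value > 5 * g.value.mean()]
    print(f"  {int(d)}-sep responders above 5x the group mean: {len(hot)}")
print(f"wrote {OUT / 'subnetwork_correlations.tsv'}")
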