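"""Distance-stratified expression-perturbation analysis (k-sep pipeline).

After depleting one miRNA (the perturbation source), its effect is expected
to attenuate along alternating paths of shared targets and target-sharing
miRNAs.  Genes are stratified by their bipartite distance from an
artificial source node attached to the perturbed miRNA: the miRNA itself is
1-sep, its direct targets 2-sep, miRNAs sharing those targets 3-sep, their
other targets 4-sep, and so on.  To reduce noise, a target at distance 2k
enters the 2k-sep group only if *every* miRNA regulating it belongs to the
defining (2k-1)-sep group; otherwise it is excluded.  Control genes are
array genes absent from the interactome altogether.

Normalized log2 fold changes of the groups are then compared with
two-sided Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import BipartiteTopology

__all__ = [
    "SepClassification",
    "GroupComparison",
    "classify_sep_groups",
    "normalize_log2fc",
    "compare_groups",
    "split_by_regulator_count",
    "tf_confound_filter",
    "read_expression_table",
    "write_expression_table",
]


@dataclass
class SepClassification:
    """Per-node distance labels and retained group membership.

    ``table`` columns: node, kind ('mirna'|'gene'|'control'), distance
    (edges from the artificial source; NaN for control/unreachable), group
    ('source', '1-sep', ..., 'excluded', 'control', 'unreachable'),
    n_defining_regulators (for retained targets: number of regulators in
    the defining miRNA group), reason (exclusion note).
    """

    source: str
    table: pd.DataFrame
    max_sep: int = 6
    notes: dict = field(default_factory=dict)

    def group(self, name: str) -> list:
        return self.table.loc[self.table["group"] == name, "node"].tolist()

    def group_sizes(self) -> dict:
        return self.table["group"].value_counts().to_dict()


def classify_sep_groups(topology: BipartiteTopology, source_mirna: str,
                        universe=None, max_sep: int = 6) -> SepClassification:
    """Label nodes by bipartite distance from the perturbation source.

    An artificial source node is attached to ``source_mirna``, so the
    perturbed miRNA is 1-sep and distances of miRNAs are odd, of targets
    even.  Labels are minimum distances.  A target at distance 2k is
    retained in the 2k-sep group only if all of its regulators are
    (2k-1)-sep (single-regulator targets qualify trivially); mixed
    regulator sets are labeled 'excluded'.  ``universe`` is the list of
    array genes; those absent from the interactome form the control group.
    """
    if source_mirna not in topology.mirnas:
        raise KeyError(f"source miRNA {source_mirna!r} not in topology")
    G = nx.Graph(topology.edges)
    G.add_nodes_from(topology.mirnas)
    G.add_nodes_from(topology.mrnas)
    dist = {n: d + 1 for n, d in
            nx.single_source_shortest_path_length(G, source_mirna).items()}
    label = {}
    for n, d in dist.items():
        label[n] = f"{d}-sep"
    rows = []
    for m in topology.mirnas:
        d = dist.get(m, np.nan)
        group = label.get(m, "unreachable")
        rows.append((m, "mirna", d, group, np.nan, ""))
    for t in topology.mrnas:
        d = dist.get(t)
        if d is None:
            rows.append((t, "gene", np.nan, "unreachable", np.nan, "disconnected"))
            continue
        regulators = list(G.neighbors(t))
        reg_labels = {label[r] for r in regulators}
        defining = f"{d - 1}-sep"
        n_def = sum(label[r] == defining for r in regulators)
        if reg_labels == {defining}:
            rows.append((t, "gene", d, f"{d}-sep", n_def, ""))
        else:
            rows.append((t, "gene", d, "excluded", n_def,
                         f"regulator labels {sorted(reg_labels)} != {{{defining}}}"))
    interactome_genes = set(topology.mrnas)
    if universe is not None:
        universe = list(universe)
        controls = [g for g in universe
                    if g not in interactome_genes and g not in set(topology.mirnas)]
        if not controls:
            warnings.warn("empty control group: every universe gene is in the interactome")
        for g in controls:
            rows.append((g, "control", np.nan, "control", np.nan, ""))
    table = pd.DataFrame(rows, columns=["node", "kind", "distance", "group",
                                        "n_defining_regulators", "reason"])
    return SepClassification(source=source_mirna, table=table, max_sep=max_sep)


# ---------------------------------------------------------------------------
# expression tables

def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene_id (or gene) and log2fc; one row per gene."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id", cols.get("gene"))
    if gene_col is None or "log2fc" not in cols:
        raise ValueError("expression table needs columns gene_id/gene and log2fc")
    out = pd.DataFrame({"gene": df[gene_col].astype(str),
                        "log2fc": df[cols["log2fc"]].astype(float)})
    if out["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    return out


def write_expression_table(records: pd.DataFrame, path) -> None:
    records[["gene", "log2fc"]].to_csv(path, sep="\t", index=False)


def normalize_log2fc(records: pd.DataFrame) -> pd.DataFrame:
    """Median-center the log2 fold changes (global median -> 0)."""
    if len(records) == 0:
        raise ValueError("no expression records")
    out = records.copy()
    out["log2fc"] = out["log2fc"] - out["log2fc"].median()
    return out


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    direction: int  # sign of median(a) - median(b)
    method: str = "asymp"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _group_values(records: pd.DataFrame, classification: SepClassification,
                  group: str) -> np.ndarray:
    genes = set(classification.group(group))
    return records.loc[records["gene"].isin(genes), "log2fc"].to_numpy()


def compare_groups(records: pd.DataFrame, classification: SepClassification,
                   pairs) -> list[GroupComparison]:
    """Two-sided two-sample K-S tests between labeled groups.

    ``pairs`` is an iterable of (group_a, group_b) label pairs, e.g.
    ('2-sep', 'control').  Genes without expression values are dropped;
    a pair with fewer than 2 values on either side is skipped with a
    warning.  Exact small-sample p-values when both n <= 25, asymptotic
    otherwise.
    """
    out = []
    for ga, gb in pairs:
        va, vb = _group_values(records, classification, ga), \
            _group_values(records, classification, gb)
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"skipping {ga} vs {gb}: group sizes {len(va)}, {len(vb)}")
            continue
        method = "exact" if (len(va) <= 25 and len(vb) <= 25) else "asymp"
        res = stats.ks_2samp(va, vb, alternative="two-sided", method=method)
        out.append(GroupComparison(
            group_a=ga, group_b=gb,
            statistic=float(res.statistic), pvalue=float(res.pvalue),
            n_a=len(va), n_b=len(vb),
            direction=int(np.sign(np.median(va) - np.median(vb))),
            method=method))
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


def split_by_regulator_count(classification: SepClassification,
                             group: str = "4-sep") -> tuple[list, list]:
    """Partition a retained target group by its defining-regulator count:
    (exactly one regulator, more than one regulator)."""
    tab = classification.table
    sub = tab[tab["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} is empty")
    single = sub.loc[sub["n_defining_regulators"] == 1, "node"].tolist()
    multi = sub.loc[sub["n_defining_regulators"] > 1, "node"].tolist()
    if not single or not multi:
        warnings.warn(f"one side of the {group} regulator-count split is empty")
    return single, multi


def tf_confound_filter(classification: SepClassification,
                       topology: BipartiteTopology,
                       tf_table: pd.DataFrame,
                       depth: int = 1) -> SepClassification:
    """Remove transcription-factor-confounded genes from the 4-sep group.

    If a 2-sep target encodes a TF activator, its transcriptional targets
    could be upregulated directly, mimicking distant-ceRNA propagation.
    This filter removes from 4-sep (i) every listed target of a TF whose
    transcript is 2-sep, and (ii) any gene sharing a miRNA regulator with
    such a target (one co-regulation step per ``depth`` unit).

    ``tf_table`` columns: tf_gene, target_gene, mode; only activator rows
    are used.  An empty table returns the classification unchanged.
    """
    new = SepClassification(source=classification.source,
                            table=classification.table.copy(),
                            max_sep=classification.max_sep,
                            notes=dict(classification.notes))
    if tf_table is None or len(tf_table) == 0:
        warnings.warn("empty TF table: classification unchanged")
        return new
    tf = tf_table
    if "mode" in tf.columns:
        tf = tf[tf["mode"] == "activator"]
    two_sep = set(classification.group("2-sep"))
    direct = set(tf.loc[tf["tf_gene"].isin(two_sep), "target_gene"])
    # expand to ceRNAs: genes sharing a miRNA regulator with a removed gene
    gene_regs: dict = {}
    for r, t in topology.edges:
        gene_regs.setdefault(t, set()).add(r)
    removed = set(direct)
    frontier = set(direct)
    for _ in range(depth):
        hit_regs = set().union(*(gene_regs.get(g, set()) for g in frontier)) \
            if frontier else set()
        frontier = {g for g, regs in gene_regs.items()
                    if regs & hit_regs} - removed
        removed |= frontier
    tab = new.table
    mask = (tab["group"] == "4-sep") & tab["node"].isin(removed)
    tab.loc[mask, "group"] = "excluded"
    tab.loc[mask, "reason"] = "tf-confound"
    new.notes["tf_confound_removed"] = sorted(tab.loc[mask, "node"])
    return new
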