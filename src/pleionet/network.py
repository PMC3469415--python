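"""Assemble and export the directed genetic influence network.

Nodes are variants and phenotypes.  Variant-to-variant edges carry the
directed influence coefficients, which are uniquely determined per pair
and need no averaging.  Variant-to-phenotype edges carry the mean of the
recomposed (original-phenotype-scale) main-effect coefficients over all
pairwise models containing the variant, with a root-mean-square error
combination of the per-model standard errors.  Only coefficients with
Holm-adjusted p below alpha become edges; edge sign encodes enhancement
(positive) versus suppression (negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "VariantPhenotypeEffect",
    "InfluenceNetwork",
    "average_effects",
    "build_network",
    "write_network",
]


@dataclass
class VariantPhenotypeEffect:
    """Averaged variant-to-phenotype coefficient over pairwise models.

    ``se`` is sqrt(mean of per-model variances) / sqrt(n_models): an
    RMS combination treated as the standard error of the mean under
    cross-model independence.  Models share the same samples, so this
    understates correlation between models; it is flagged as an
    approximation in exported metadata.
    """

    variant: str
    phenotype: str
    coef: float
    se: float
    n_models: int
    stat: float = np.nan
    p_raw: float = np.nan
    p_adj: float = np.nan


def average_effects(per_model: dict) -> list:
    """Average recomposed variant-to-phenotype coefficients across models.

    ``per_model`` maps (variant, phenotype) -> list of (coef, var) pairs,
    one entry per estimable pairwise model containing the variant.
    Variants appearing in no estimable model are simply absent.
    """
    out = []
    for (variant, phenotype), entries in per_model.items():
        coefs = np.array([c for c, _ in entries], dtype=float)
        vars_ = np.array([v for _, v in entries], dtype=float)
        m = len(entries)
        mean = float(coefs.mean())
        se = float(np.sqrt(vars_.mean()) / np.sqrt(m))
        stat = abs(mean) / se if se > 0 else np.inf
        out.append(VariantPhenotypeEffect(variant, phenotype, mean, se, m, stat))
    return out


@dataclass
class InfluenceNetwork:
    """Significance-filtered directed influence network."""

    graph: nx.DiGraph
    alpha: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        cols = ["source", "target", "type", "coef", "sign", "weight", "se", "p_adj"]
        return pd.DataFrame(rows, columns=cols)


def build_network(influences, effects, alpha: float = 0.05) -> InfluenceNetwork:
    """Retain coefficients with adjusted p < alpha as directed edges.

    ``influences`` is a list of InfluencePair (variant-to-variant edges,
    taken directly from each pair's model); ``effects`` a list of
    VariantPhenotypeEffect (averaged variant-to-phenotype edges).
    Nodes for every variant and phenotype are always present, so an
    all-insignificant analysis yields a node-only network.
    """
    g = nx.DiGraph()
    for ip in influences:
        for locus in ip.pair:
            g.add_node(str(locus), kind="variant")
    for eff in effects:
        g.add_node(str(eff.variant), kind="variant")
        g.add_node(str(eff.phenotype), kind="phenotype")

    for ip in influences:
        p_adj = ip.p_adj if ip.p_adj is not None else [np.nan, np.nan]
        p_raw = ip.p_raw if ip.p_raw is not None else [np.nan, np.nan]
        l1, l2 = (str(x) for x in ip.pair)
        # gamma[0] = influence of locus 2 on locus 1, edge l2 -> l1
        for d, (src, dst) in enumerate([(l2, l1), (l1, l2)]):
            if ip.valid[d] and np.isfinite(p_adj[d]) and p_adj[d] < alpha:
                coef = float(ip.gamma[d])
                g.add_edge(src, dst, type="variant-variant", coef=coef,
                           sign=int(np.sign(coef)), weight=abs(coef),
                           se=float(ip.se[d]), p_raw=float(p_raw[d]),
                           p_adj=float(p_adj[d]))
    for eff in effects:
        if np.isfinite(eff.p_adj) and eff.p_adj < alpha:
            g.add_edge(str(eff.variant), str(eff.phenotype),
                       type="variant-phenotype", coef=float(eff.coef),
                       sign=int(np.sign(eff.coef)), weight=abs(float(eff.coef)),
                       se=float(eff.se), p_raw=float(eff.p_raw),
                       p_adj=float(eff.p_adj))
    meta = {
        "alpha": alpha,
        "note": ("variant-phenotype SEs use an RMS cross-model combination "
                 "assuming model independence; models share samples, so "
                 "correlation is understated"),
    }
    return InfluenceNetwork(g, alpha, meta)


def write_network(net: InfluenceNetwork, path, fmt: str = "tsv") -> None:
    """Write the network as ``tsv`` (edge list), ``graphml`` or ``sif``.

    SIF labels edges "activates" (positive coefficient) or "suppresses"
    (negative); isolated nodes are emitted as single-column lines.
    """
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            linked = set()
            for u, v, d in net.graph.edges(data=True):
                label = "activates" if d["coef"] > 0 else "suppresses"
                fh.write(f"{u}\t{label}\t{v}\n")
                linked |= {u, v}
            for node in net.graph.nodes:
                if node not in linked:
                    fh.write(f"{node}\n")
    elif fmt == "tsv":
        net.edges_dataframe().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use sif, graphml or tsv)")
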