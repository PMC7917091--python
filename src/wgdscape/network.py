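"""Coexpression modules and the signed gene-metabolite correlation network.

Genes are grouped into tissue-aligned coexpression modules by hierarchical
clustering on correlation distance (1 - Pearson), each module labelled by
the tissue where its genes are most expressed.  Gene-metabolite edges are
Pearson correlations across shared samples, kept when |r| strictly exceeds
the cutoff (default 0.7) and signed: positive edges connect, e.g.,
flower/glandular-trichome genes to attractant terpenoids, negative edges to
repellents.

Expression values are log2(x+1)-transformed before any correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationEdge",
    "cluster_modules",
    "correlate",
    "edges_to_graph",
    "write_edges",
]

SINK_MODULE = "unassigned"


@dataclass(frozen=True)
class CorrelationEdge:
    source: str  # gene id
    target: str  # metabolite id
    r: float
    sign: str  # 'positive' | 'negative'

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.sign != ("positive" if self.r > 0 else "negative"):
            raise ValueError("sign must match sign(r)")


def _log2p1(df: pd.DataFrame) -> pd.DataFrame:
    return np.log2(df.astype(float) + 1.0)


def cluster_modules(
    expr: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    k: int = 5,
    linkage_method: str = "average",
) -> dict[str, str]:
    """Group genes into ``k`` coexpression modules labelled by tissue.

    ``expr`` is genes x samples (TPM-like).  Distance is 1 - Pearson over
    log2(x+1) profiles, clustered hierarchically (``linkage_method``) and
    cut to ``k`` clusters.  Each module is labelled by the tissue with the
    highest mean within-module expression; duplicate tissue labels get a
    numeric suffix.  Zero-variance genes go to a sink module.
    """
    if len(expr) < k:
        raise ValueError(f"need >= {k} genes, got {len(expr)}")
    log_expr = _log2p1(expr)
    variances = log_expr.var(axis=1)
    constant = variances[variances <= 1e-12].index
    usable = log_expr.drop(index=constant)
    if constant.size:
        warnings.warn(f"{constant.size} constant-expression gene(s) in sink module",
                      stacklevel=2)
    if len(usable) < k:
        raise ValueError("too few variable genes for requested k")

    corr = np.corrcoef(usable.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    tissues = sorted(set(sample_tissue.values()))
    tissue_samples = {
        t: [s for s in expr.columns if sample_tissue[s] == t] for t in tissues
    }
    module_label: dict[int, str] = {}
    used: dict[str, int] = {}
    for cluster_id in sorted(set(labels)):
        genes = usable.index[labels == cluster_id]
        means = {
            t: float(log_expr.loc[genes, cols].to_numpy().mean())
            for t, cols in tissue_samples.items()
            if cols
        }
        best = max(sorted(means), key=lambda t: means[t])
        n = used.get(best, 0)
        used[best] = n + 1
        module_label[cluster_id] = best if n == 0 else f"{best}_{n + 1}"

    out = {g: module_label[c] for g, c in zip(usable.index, labels)}
    for g in constant:
        out[g] = SINK_MODULE
    return out


def correlate(
    expr: pd.DataFrame,
    metabolites: pd.DataFrame,
    threshold: float = 0.7,
    log_transform_expr: bool = True,
) -> list[CorrelationEdge]:
    """Signed gene-metabolite Pearson edges over shared samples.

    Edges are kept iff |r| > ``threshold`` — strictly, so a pair at exactly
    the cutoff is excluded.  Zero-variance genes or metabolites are skipped
    with a warning; fewer than 3 shared samples is an error.
    """
    shared = [s for s in expr.columns if s in set(metabolites.columns)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples (< 3)")
    X = _log2p1(expr[shared]) if log_transform_expr else expr[shared].astype(float)
    M = metabolites[shared].astype(float)

    x = X.to_numpy()
    m = M.to_numpy()
    x_sd = x.std(axis=1)
    m_sd = m.std(axis=1)
    skip_x = x_sd <= 1e-12
    skip_m = m_sd <= 1e-12
    if skip_x.any() or skip_m.any():
        warnings.warn(
            f"skipped {int(skip_x.sum())} zero-variance gene(s) and "
            f"{int(skip_m.sum())} zero-variance metabolite(s)",
            stacklevel=2,
        )
    xz = (x - x.mean(axis=1, keepdims=True))
    mz = (m - m.mean(axis=1, keepdims=True))
    n = len(shared)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xz @ mz.T) / (n * np.outer(x_sd, m_sd))

    edges: list[CorrelationEdge] = []
    for i, gene in enumerate(X.index):
        if skip_x[i]:
            continue
        for j, met in enumerate(M.index):
            if skip_m[j]:
                continue
            rij = float(np.clip(r[i, j], -1.0, 1.0))
            if abs(rij) > threshold:
                edges.append(
                    CorrelationEdge(
                        source=str(gene),
                        target=str(met),
                        r=rij,
                        sign="positive" if rij > 0 else "negative",
                    )
                )
    return edges


def edges_to_graph(
    edges: list[CorrelationEdge],
    modules: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Cytoscape-importable graph; node attribute ``kind`` separates genes
    from metabolites, ``module`` carries coexpression labels when given."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.source, kind="gene",
                   module=(modules or {}).get(e.source, ""))
        g.add_node(e.target, kind="metabolite", module="")
        g.add_edge(e.source, e.target, r=e.r, sign=e.sign)
    return g


def write_edges(edges: list[CorrelationEdge], path) -> None:
    pd.DataFrame(
        [dict(source=e.source, target=e.target, r=e.r, sign=e.sign) for e in edges],
        columns=["source", "target", "r", "sign"],
    ).to_csv(path, sep="\t", index=False)
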