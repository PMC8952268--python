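"""Spearman co-occurrence network over ASVs and abiotic process parameters.

Pairwise Spearman rank correlations (average ranks on ties, two-sided p from
the t-approximation) over rarefied ASV abundances and abiotic columns (HRT,
concentrations, productivities, yields); edges require |rho| > 0.7 and
BH-adjusted p < 0.05 over the family of all unique off-diagonal pairs.
Export to GEXF/GraphML for Gephi.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diversity import fdr_adjust
from .tables import TableError

#: default thresholds for a statistically robust edge
RHO_CUTOFF = 0.7
P_CUTOFF = 0.05


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    rho_cutoff: float = RHO_CUTOFF
    p_cutoff: float = P_CUTOFF

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"u": u, "v": v, "rho": d["rho"], "p_adj": d["p_adj"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["u", "v", "rho", "p_adj", "sign"])

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree)).sort_values(ascending=False)

    def hubs(self, n: int = 5) -> list[str]:
        return list(self.degrees().index[:n])


def spearman_matrix(columns: pd.DataFrame, min_obs: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p over the columns of a DataFrame.

    Constant columns have undefined correlations; their entries are NaN.
    """
    if len(columns) < min_obs:
        raise TableError(f"need at least {min_obs} paired observations")
    names = list(columns.columns)
    x = columns.to_numpy(dtype=float)
    constant = np.std(x, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(x)
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    for i in np.flatnonzero(constant):
        rho[i, :] = rho[:, i] = np.nan
        p[i, :] = p[:, i] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


def adjust_pair_pvalues(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust the upper-triangle p-values as one family; mirror back."""
    names = list(p.columns)
    iu = np.triu_indices(len(names), k=1)
    raw = p.to_numpy()[iu]
    adj = np.full_like(raw, np.nan)
    ok = ~np.isnan(raw)
    if ok.any():
        adj[ok] = fdr_adjust(raw[ok])
    out = np.full(p.shape, np.nan)
    out[iu] = adj
    out.T[iu] = adj
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=names, columns=names)


def build_network(
    rho: pd.DataFrame,
    p_adj: pd.DataFrame,
    rho_cutoff: float = RHO_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    node_types: dict[str, str] | None = None,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrix into an undirected signed network.

    Edges require |rho| strictly above ``rho_cutoff`` AND adjusted p strictly
    below ``p_cutoff``.
    """
    names = list(rho.columns)
    g = nx.Graph()
    for n in names:
        g.add_node(n, type=(node_types or {}).get(n, "ASV"))
    r = rho.to_numpy()
    q = p_adj.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isnan(r[i, j]) or np.isnan(q[i, j]):
                continue
            if abs(r[i, j]) > rho_cutoff and q[i, j] < p_cutoff:
                g.add_edge(
                    names[i], names[j],
                    rho=float(r[i, j]), p_adj=float(q[i, j]),
                    sign="positive" if r[i, j] > 0 else "negative",
                    weight=float(abs(r[i, j])),
                )
    return CooccurrenceNetwork(g, rho_cutoff, p_cutoff)


def cooccurrence_network(
    asv_counts: pd.DataFrame,
    abiotic: pd.DataFrame,
    rho_cutoff: float = RHO_CUTOFF,
    p_cutoff: float = P_CUTOFF,
) -> CooccurrenceNetwork:
    """Full pipeline: rarefied ASV counts + abiotic columns -> thresholded network."""
    combined = pd.concat([asv_counts, abiotic.loc[asv_counts.index]], axis=1)
    rho, p = spearman_matrix(combined)
    node_types = {c: "ASV" for c in asv_counts.columns}
    node_types.update({c: "abiotic" for c in abiotic.columns})
    return build_network(rho, adjust_pair_pvalues(p), rho_cutoff, p_cutoff, node_types)


def export_gexf(network: CooccurrenceNetwork, path: str | Path) -> None:
    """Write the network as GEXF (Gephi-loadable)."""
    nx.write_gexf(network.graph, str(path))


def export_graphml(network: CooccurrenceNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))


def export_edge_list(network: CooccurrenceNetwork, path: str | Path) -> None:
    network.edges.to_csv(Path(path), sep="\t", index=False)
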