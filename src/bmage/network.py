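"""Multi-organ correlation network of differential metabolites.

Nodes are (organ, feature) pairs; an undirected edge joins two nodes
when the correlation of their normalized log intensities across the
aligned animals satisfies |r| > r_thresh and p < p_thresh (defaults
0.8 and 0.05). Correlations may cross organs because every animal
contributes one sample per organ; animals missing any organ are
dropped listwise. Organ hubness is summarized by aggregate degree.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DomainError
from .metabolomics import MetaboliteMatrix, normalize_log_median

__all__ = [
    "build_correlation_graph",
    "correlation_network",
    "organ_hub_summary",
    "write_edge_list",
    "CorrelationNetworkBuilder",
]

NODE_SEP = "::"


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t-distribution transform."""
    if n <= 2:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))


def build_correlation_graph(
    values: pd.DataFrame,
    node_attrs: Mapping[str, dict] | None = None,
    r_thresh: float = 0.8,
    p_thresh: float = 0.05,
    method: str = "pearson",
) -> nx.Graph:
    """Threshold the pairwise correlation of a samples x nodes table.

    NaN entries are handled pairwise-complete. Constant columns cannot
    be correlated; they are skipped with a warning and enter the graph
    as isolated nodes.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    if values.shape[0] < 4:
        raise DomainError(f"need at least 4 aligned samples, got {values.shape[0]}")
    graph = nx.Graph(r_thresh=r_thresh, p_thresh=p_thresh, method=method)
    node_attrs = node_attrs or {}
    for node in values.columns:
        graph.add_node(node, **node_attrs.get(node, {}))

    constant = values.columns[values.std(skipna=True).fillna(0.0) == 0.0]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant feature(s) skipped in correlation network",
            stacklevel=2,
        )
    usable = [c for c in values.columns if c not in set(constant)]
    sub = values[usable]
    corr = sub.corr(method=method, min_periods=3)
    present = sub.notna().to_numpy()
    pair_n = present.T.astype(int) @ present.astype(int)

    cols = list(sub.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iat[i, j]
            if np.isnan(r) or abs(r) <= r_thresh:
                continue
            p = _corr_pvalue(float(r), int(pair_n[i, j]))
            if np.isnan(p) or p >= p_thresh:
                continue
            graph.add_edge(cols[i], cols[j], r=float(r), p=p)
    return graph


def correlation_network(
    matrices: Mapping[str, MetaboliteMatrix],
    features: Mapping[str, Sequence[str]],
    r_thresh: float = 0.8,
    p_thresh: float = 0.05,
    method: str = "pearson",
    directions: Mapping[str, Mapping[str, str]] | None = None,
) -> nx.Graph:
    """Correlation network across organs on listwise-aligned animals.

    ``features`` selects the differential features per organ; node ids
    are ``"<organ>::<feature>"``. Correlations are computed on
    normalized log intensities over the animals present in every organ.
    """
    organs = [o for o in matrices if len(features.get(o, ())) > 0]
    if not organs:
        raise DomainError("no features selected for any organ")
    shared: set[str] | None = None
    for organ in organs:
        ids = set(matrices[organ].sample_ids)
        shared = ids if shared is None else shared & ids
    shared_ids = sorted(shared or set())
    if len(shared_ids) < 4:
        raise DomainError(f"only {len(shared_ids)} animals shared across organs; need >= 4")

    blocks = []
    node_attrs: dict[str, dict] = {}
    for organ in organs:
        m = matrices[organ]
        norm = normalize_log_median(m).loc[shared_ids, list(features[organ])]
        norm.columns = [f"{organ}{NODE_SEP}{f}" for f in norm.columns]
        for feat in features[organ]:
            node = f"{organ}{NODE_SEP}{feat}"
            attrs = {"organ": organ, "feature_id": str(feat)}
            if directions and feat in directions.get(organ, {}):
                attrs["direction"] = directions[organ][feat]
            node_attrs[node] = attrs
        blocks.append(norm)
    values = pd.concat(blocks, axis=1)
    return build_correlation_graph(values, node_attrs, r_thresh, p_thresh, method)


def organ_hub_summary(graph: nx.Graph) -> pd.DataFrame:
    """Aggregate degree statistics per organ, ranked by total degree."""
    rows: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        organ = data.get("organ", node.split(NODE_SEP)[0] if NODE_SEP in str(node) else "")
        entry = rows.setdefault(
            organ, {"n_nodes": 0, "n_edges": 0, "total_degree": 0}
        )
        entry["n_nodes"] += 1
        entry["total_degree"] += graph.degree(node)
    for u, v in graph.edges():
        for organ in {graph.nodes[u].get("organ"), graph.nodes[v].get("organ")}:
            if organ in rows:
                rows[organ]["n_edges"] += 1
    if not rows:
        return pd.DataFrame(
            columns=["n_nodes", "n_edges", "total_degree", "mean_degree"]
        )
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary["mean_degree"] = summary["total_degree"] / summary["n_nodes"].clip(lower=1)
    # rank by total degree; on ties the denser (hub-like) organ first
    summary = summary.sort_values(
        ["total_degree", "mean_degree"], ascending=False, kind="mergesort"
    )
    summary.index.name = "organ"
    return summary


def write_edge_list(graph: nx.Graph, path) -> None:
    """TSV edge list (node_a, node_b, r, p) sorted for reproducibility."""
    rows = [
        {"node_a": u, "node_b": v, "r": d["r"], "p": d["p"]}
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p"])
    if len(df):
        df = df.sort_values(["node_a", "node_b"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class CorrelationNetworkBuilder(BaseEstimator):
    """Estimator form of :func:`correlation_network`.

    Attributes
    ----------
    graph_ : nx.Graph
    summary_ : pd.DataFrame
        Output of :func:`organ_hub_summary`.
    """

    def __init__(
        self,
        r_thresh: float = 0.8,
        p_thresh: float = 0.05,
        method: str = "pearson",
    ) -> None:
        self.r_thresh = r_thresh
        self.p_thresh = p_thresh
        self.method = method

    def fit(
        self,
        X: Mapping[str, MetaboliteMatrix],
        y: Mapping[str, Sequence[str]] = None,
    ) -> "CorrelationNetworkBuilder":
        if y is None:
            raise DomainError("pass the per-organ feature selection as y")
        self.graph_ = correlation_network(
            X, y, self.r_thresh, self.p_thresh, self.method
        )
        self.summary_ = organ_hub_summary(self.graph_)
        return self
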