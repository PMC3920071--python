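"""Weighted graph-theory measures of connectivity matrices.

The symmetric connectivity matrix of a hemisphere (or of the full bilateral
network) is treated as a weighted undirected graph; a zero weight means the
edge is absent.  Shortest-path measures convert weights to lengths as
l(i, j) = 1 / w(i, j), the standard convention for connectivity-strength
weights (stronger connection = shorter path); this conversion is a modeling
choice and is applied consistently across betweenness and efficiency.

Measures
--------
strength
    Sum of a node's edge weights (diagonal excluded).
betweenness centrality
    Fraction of shortest paths between all other node pairs that pass
    through the node, with full shortest-path multiplicity counting;
    normalized by (n-1)(n-2)/2 by default (raw path counts via a flag).
clustering coefficient
    Onnela geometric-mean weighted clustering: weights rescaled by the graph
    maximum, C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)) with
    k_i the binary degree; 0 when k_i < 2.
weighted global efficiency
    Mean of 1 / d(i, j) over all ordered node pairs, with disconnected pairs
    contributing 0; equals 1 for a complete graph of unit weights.

Betweenness and clustering are scale invariant (multiplying all weights by
c > 0 changes nothing); efficiency scales linearly with c.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .cohort import Cohort
from .errors import ValidationError
from .matrices import ConnectivityMatrix


def _as_weights(m) -> np.ndarray:
    w = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"graph metrics need a square matrix, got shape {w.shape}")
    if np.any(w < 0):
        raise ValidationError("graph metrics need nonnegative weights")
    if not np.allclose(w, w.T, atol=1e-8, rtol=0):
        raise ValidationError("graph metrics need a symmetric matrix; symmetrize first")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def _graph(w: np.ndarray) -> nx.Graph:
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from((int(i), int(j), float(w[i, j])) for i, j in zip(iu, ju))
    for i, j in g.edges:
        g[i][j]["length"] = 1.0 / g[i][j]["weight"]
    return g


def node_strength(m) -> np.ndarray:
    """Row sums of the weight matrix, diagonal excluded."""
    return _as_weights(m).sum(axis=1)


def betweenness(m, normalized: bool = True) -> np.ndarray:
    """Weighted betweenness centrality on 1/w shortest-path lengths."""
    w = _as_weights(m)
    bc = nx.betweenness_centrality(_graph(w), normalized=normalized, weight="length")
    return np.array([bc[i] for i in range(w.shape[0])])


def clustering(m) -> np.ndarray:
    """Onnela weighted clustering coefficient (weights rescaled by max)."""
    w = _as_weights(m)
    cc = nx.clustering(_graph(w), weight="weight")
    return np.array([cc[i] for i in range(w.shape[0])])


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def global_efficiency(m) -> float:
    """Mean inverse shortest-path length over all node pairs."""
    w = _as_weights(m)
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(_length_matrix(w), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def subject_metrics(cohort: Cohort, layout: str = "intra_left") -> pd.DataFrame:
    """Per-subject per-node metric table plus a per-subject efficiency column.

    Columns: subject_id, group, node, strength, betweenness, clustering,
    global_efficiency (repeated per node for convenience).
    """
    mats = cohort.matrices.get(layout)
    if mats is None:
        raise ValidationError(f"cohort has no matrices for layout {layout!r}")
    if layout == "commissural":
        raise ValidationError("graph metrics need a symmetric layout (intra or bilateral)")
    rows = []
    labels = mats[0].row_labels
    for subj, m in zip(cohort.subjects, mats):
        s = node_strength(m)
        b = betweenness(m)
        c = clustering(m)
        eff = global_efficiency(m)
        for k, lab in enumerate(labels):
            rows.append(
                {
                    "subject_id": subj.id,
                    "group": subj.group,
                    "node": lab,
                    "strength": s[k],
                    "betweenness": b[k],
                    "clustering": c[k],
                    "global_efficiency": eff,
                }
            )
    return pd.DataFrame(rows)


def metric_group_tests(cohort: Cohort, layout: str = "intra_left") -> pd.DataFrame:
    """Per-node group t-tests and severity correlations of graph metrics.

    Two-tailed t-tests between groups per node and metric, plus Spearman
    correlations with severity across case subjects.  P-values are
    uncorrected and exploratory by design; the table carries an explicit
    ``uncorrected`` flag column.
    """
    cohort.require_groups()
    table = subject_metrics(cohort, layout)
    case_ids = {s.id for s in cohort.subjects if s.group == "case"}
    sev = {s.id: s.severity for s in cohort.subjects}
    rows = []
    for metric in ("strength", "betweenness", "clustering"):
        wide = table.pivot(index="subject_id", columns="node", values=metric)
        is_case = np.array([i in case_ids for i in wide.index])
        sev_vec = np.array(
            [np.nan if sev[i] is None else sev[i] for i in wide.index], dtype=float
        )
        for node in wide.columns:
            vals = wide[node].to_numpy()
            a, b = vals[is_case], vals[~is_case]
            if len(a) < 2 or len(b) < 2:
                raise ValidationError("metric group tests need >= 2 subjects per group")
            t, p = stats.ttest_ind(a, b)
            if np.isnan(p):  # zero variance in both groups
                t, p = 0.0, 1.0
            sev_mask = is_case & ~np.isnan(sev_vec)
            if sev_mask.sum() >= 4 and np.ptp(vals[sev_mask]) > 0 and np.ptp(sev_vec[sev_mask]) > 0:
                rho, p_rho = stats.spearmanr(vals[sev_mask], sev_vec[sev_mask])
            else:
                rho, p_rho = np.nan, np.nan
            rows.append(
                {
                    "metric": metric,
                    "node": node,
                    "mean_case": a.mean(),
                    "mean_control": b.mean(),
                    "t": t,
                    "p_two": p,
                    "severity_rho": rho,
                    "severity_p": p_rho,
                    "uncorrected": True,
                }
            )
    return pd.DataFrame(rows)
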