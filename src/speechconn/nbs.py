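"""Permutation inference over connectivity matrices.

Two family-wise-error-controlling procedures, both built on random
permutation of the exchangeable unit:

* the network-based statistic (NBS): edge-wise statistics are thresholded at
  an uncorrected one-tailed p, connected components of supra-threshold edges
  are extracted, and each observed component's size (edge count) is referred
  to the permutation null distribution of the *maximum* component size;
* a sign-bias ratio test: counts the negative vs positive signs of the
  edge-wise effect over a scope of edges and tests whether the
  Laplacian-corrected ratio R = (n_neg + 1) / (n_pos + 1) is larger than
  expected under exchangeability.  A binomial test would be wrong here:
  edges sharing a seed or target region are strongly dependent, and the
  permutation null inherits that dependence while the binomial null assumes
  it away.

Corrected p-values use the (1 + b) / (1 + m) estimator over m permutations,
so they are never smaller than 1/(m + 1) and never exactly zero.  Tails
follow the one-tailed conventions of the group study the package supports:
group tests look for case < control, correlations for negative rho, and the
sign-bias test for an excess of negative signs, all at alpha = 0.05.

Inside permutations the rank-sum statistic always uses the tie-corrected
normal approximation (never exact enumeration) so that ranks can be computed
once and every permutation reduces to a matrix product.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .edgewise import (
    _rank_columns,
    _standardize_columns,
    _tie_terms,
    _z_to_pvalues,
    ranksum_edges,
    ranksum_normal,
    spearman_edges,
    spearman_rho,
    _rho_to_pvalues,
)
from .errors import ValidationError

TAILS = ("case_lt_control", "case_gt_control", "negative_correlation", "positive_correlation")

_TAIL_COLUMN = {
    "case_lt_control": "p_one_neg",
    "case_gt_control": "p_one_pos",
    "negative_correlation": "p_one_neg",
    "positive_correlation": "p_one_pos",
}


@dataclass
class PermutationPlan:
    """Permutation-test settings.

    Defaults follow the analysis conventions the package supports: 10,000
    iterations, one-tailed alpha 0.05, edge p threshold 0.01 for group NBS
    (0.05 is the convention for correlation NBS; pass it explicitly or use
    :func:`nbs_correlation`'s default plan).
    """

    n_iterations: int = 10_000
    edge_p_threshold: float = 0.01
    tail: str = "case_lt_control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ValidationError(f"n_iterations must be >= 100, got {self.n_iterations}")
        if not (0.0 < self.edge_p_threshold < 1.0):
            raise ValidationError(
                f"edge_p_threshold must be in (0, 1), got {self.edge_p_threshold}"
            )
        if self.tail not in TAILS:
            raise ValidationError(f"tail must be one of {TAILS}, got {self.tail!r}")


@dataclass
class ComponentResult:
    """A connected set of supra-threshold edges with its permutation p."""

    edges: list[tuple[str, str]]
    nodes: list[str]
    size: int
    corrected_p: float | None
    tail: str

    def to_dict(self) -> dict:
        return {
            "edges": [list(e) for e in self.edges],
            "nodes": list(self.nodes),
            "size": self.size,
            "corrected_p": self.corrected_p,
            "tail": self.tail,
        }


@dataclass
class SignBiasResult:
    """Observed sign counts, Laplacian-corrected ratio, and permutation p."""

    n_neg: int
    n_pos: int
    ratio: float
    corrected_p: float
    count_scope: str
    n_scope_edges: int
    tail: str = "negative_bias"

    def to_dict(self) -> dict:
        return {
            "n_neg": self.n_neg,
            "n_pos": self.n_pos,
            "ratio": self.ratio,
            "corrected_p": self.corrected_p,
            "count_scope": self.count_scope,
            "n_scope_edges": self.n_scope_edges,
            "tail": self.tail,
        }


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _components_from_edges(
    u: np.ndarray, v: np.ndarray, mask: np.ndarray, n_nodes: int
) -> list[np.ndarray]:
    """Connected components of the supra-threshold edge graph.

    Returns, for each component, the array of *edge indices* belonging to it,
    ordered largest component first with ties broken by smallest node index.
    """
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    uf = _UnionFind(n_nodes)
    for k in idx:
        uf.union(int(u[k]), int(v[k]))
    roots: dict[int, list[int]] = {}
    for k in idx:
        roots.setdefault(uf.find(int(u[k])), []).append(int(k))
    comps = list(roots.values())
    comps.sort(key=lambda ks: (-len(ks), min(min(u[k], v[k]) for k in ks)))
    return [np.array(ks, dtype=int) for ks in comps]


def _max_component_size(u: np.ndarray, v: np.ndarray, mask: np.ndarray, n_nodes: int) -> int:
    comps = _components_from_edges(u, v, mask, n_nodes)
    return len(comps[0]) if comps else 0


def extract_components(
    stat_table: pd.DataFrame,
    threshold: float,
    tail: str = "case_lt_control",
) -> list[ComponentResult]:
    """Threshold an edge table at a one-tailed p and extract components.

    Components are returned largest first (ties broken by smallest node
    index) with ``corrected_p`` unset; permutation correction is applied by
    :func:`nbs_group` / :func:`nbs_correlation`.
    """
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}, got {tail!r}")
    p = stat_table[_TAIL_COLUMN[tail]].to_numpy()
    labels_i = stat_table["node_i"].to_numpy()
    labels_j = stat_table["node_j"].to_numpy()
    nodes = pd.unique(np.concatenate([labels_i, labels_j]))
    node_id = {lab: k for k, lab in enumerate(nodes)}
    u = np.array([node_id[x] for x in labels_i])
    v = np.array([node_id[x] for x in labels_j])
    mask = p < threshold
    results = []
    for edge_idx in _components_from_edges(u, v, mask, len(nodes)):
        edges = [(str(labels_i[k]), str(labels_j[k])) for k in edge_idx]
        comp_nodes = sorted({n for e in edges for n in e})
        results.append(
            ComponentResult(
                edges=edges,
                nodes=comp_nodes,
                size=len(edges),
                corrected_p=None,
                tail=tail,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Permutation engines
# ---------------------------------------------------------------------------

def _permutation_label_masks(
    n_subjects: int, n_case: int, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """(P, S) boolean case-label assignments, uniformly random."""
    order = np.argsort(rng.random((n_iterations, n_subjects)), axis=1)
    masks = np.zeros((n_iterations, n_subjects), dtype=bool)
    np.put_along_axis(masks, order[:, :n_case], True, axis=1)
    return masks


def _corrected_p(perm_stats: np.ndarray, observed: float) -> float:
    m = perm_stats.shape[0]
    return float((1 + np.sum(perm_stats >= observed)) / (1 + m))


def _group_perm_one_tailed_p(
    X: np.ndarray, masks: np.ndarray, tail: str
) -> np.ndarray:
    """(P, E) one-tailed rank-sum p's for each permuted label assignment."""
    ranks = _rank_columns(X)
    tie = _tie_terms(X)
    z, degenerate = ranksum_normal(ranks, masks, tie)
    p_two, p_neg, p_pos = _z_to_pvalues(z, degenerate)
    return p_neg if tail == "case_lt_control" else p_pos


def nbs_group(
    cohort: Cohort, layout: str = "intra_left", plan: PermutationPlan | None = None
) -> list[ComponentResult]:
    """NBS group comparison: maximum-component-size permutation correction.

    Observed components come from one-tailed edge p's at the plan threshold;
    the null distribution records, for each random relabeling of subjects,
    the size of the largest supra-threshold component.
    """
    if plan is None:
        plan = PermutationPlan()
    if plan.tail not in ("case_lt_control", "case_gt_control"):
        raise ValidationError(f"group NBS needs a group tail, got {plan.tail!r}")
    cohort.require_groups()
    X, u, v, n_nodes = cohort.edge_data(layout)
    case = cohort.case_mask

    observed_table = ranksum_edges(cohort, layout, exact="never")
    components = extract_components(observed_table, plan.edge_p_threshold, plan.tail)

    rng = np.random.default_rng(plan.seed)
    masks = _permutation_label_masks(X.shape[0], int(case.sum()), plan.n_iterations, rng)
    p_perm = _group_perm_one_tailed_p(X, masks, plan.tail)
    null_max = np.array(
        [_max_component_size(u, v, p_perm[i] < plan.edge_p_threshold, n_nodes)
         for i in range(plan.n_iterations)]
    )
    for comp in components:
        comp.corrected_p = _corrected_p(null_max, comp.size)
    return components


def nbs_correlation(
    cohort: Cohort, layout: str = "intra_left", plan: PermutationPlan | None = None
) -> list[ComponentResult]:
    """NBS on severity correlations; the permutation unit is the severity
    vector, shuffled across the case subjects."""
    if plan is None:
        plan = PermutationPlan(edge_p_threshold=0.05, tail="negative_correlation")
    if plan.tail not in ("negative_correlation", "positive_correlation"):
        raise ValidationError(f"correlation NBS needs a correlation tail, got {plan.tail!r}")
    mask = cohort.require_severity()
    X, u, v, n_nodes = cohort.edge_data(layout)
    Xs = X[mask]
    sev = cohort.severities[mask]
    n = Xs.shape[0]

    observed_table = spearman_edges(cohort, layout, cases_only=True)
    components = extract_components(observed_table, plan.edge_p_threshold, plan.tail)

    wr = _rank_columns(Xs)
    Zw, const_w = _standardize_columns(wr)
    sr = stats.rankdata(sev)
    zs = (sr - sr.mean()) / (sr.std() if sr.std() > 0 else 1.0)

    rng = np.random.default_rng(plan.seed)
    perm_idx = np.argsort(rng.random((plan.n_iterations, n)), axis=1)
    Zs_perm = zs[perm_idx]  # (P, S)
    rho = spearman_rho(Zw, Zs_perm)
    rho[:, const_w] = 0.0
    p_two, p_neg, p_pos = _rho_to_pvalues(rho, n)
    p_one = p_neg if plan.tail == "negative_correlation" else p_pos
    p_one[:, const_w] = 1.0
    null_max = np.array(
        [_max_component_size(u, v, p_one[i] < plan.edge_p_threshold, n_nodes)
         for i in range(plan.n_iterations)]
    )
    for comp in components:
        comp.corrected_p = _corrected_p(null_max, comp.size)
    return components


def sign_bias_test(
    cohort: Cohort,
    layout: str = "intra_left",
    plan: PermutationPlan | None = None,
    count_scope: str = "significant_edges",
    statistic: str = "group",
    scope_p_threshold: float = 0.05,
) -> SignBiasResult:
    """Permutation test for a bias toward negative edge-effect signs.

    ``statistic`` is "group" (sign of mean(case) - mean(control) per edge) or
    "correlation" (sign of the Spearman rho with severity).  ``count_scope``
    is "all_edges" or "significant_edges" (restrict to edges with two-tailed
    p < ``scope_p_threshold``).  The statistic is the Laplacian-corrected
    ratio R = (n_neg + 1) / (n_pos + 1); the corrected p is one-tailed for an
    excess of negative signs, from the same permutation scheme as the
    corresponding NBS test.
    """
    if plan is None:
        plan = PermutationPlan()
    if count_scope not in ("all_edges", "significant_edges"):
        raise ValidationError(f"count_scope must be all_edges or significant_edges")
    if statistic not in ("group", "correlation"):
        raise ValidationError(f"statistic must be group or correlation")

    X, u, v, n_nodes = cohort.edge_data(layout)
    rng = np.random.default_rng(plan.seed)

    if statistic == "group":
        cohort.require_groups()
        case = cohort.case_mask
        n1, n2 = int(case.sum()), int((~case).sum())
        masks = _permutation_label_masks(X.shape[0], n1, plan.n_iterations, rng)
        all_masks = np.vstack([case[None, :], masks])
        # signed effect: difference of group means per assignment
        diff = (all_masks.astype(float) @ X) / n1 - ((~all_masks).astype(float) @ X) / n2
        signs = np.sign(diff)
        if count_scope == "significant_edges":
            ranks = _rank_columns(X)
            tie = _tie_terms(X)
            z, degenerate = ranksum_normal(ranks, all_masks, tie)
            p_two, _, _ = _z_to_pvalues(z, degenerate)
            in_scope = p_two < scope_p_threshold
        else:
            in_scope = np.ones_like(signs, dtype=bool)
    else:
        mask = cohort.require_severity()
        Xs = X[mask]
        sev = cohort.severities[mask]
        n = Xs.shape[0]
        wr = _rank_columns(Xs)
        Zw, const_w = _standardize_columns(wr)
        sr = stats.rankdata(sev)
        zs = (sr - sr.mean()) / (sr.std() if sr.std() > 0 else 1.0)
        perm_idx = np.argsort(rng.random((plan.n_iterations, n)), axis=1)
        all_zs = np.vstack([zs[None, :], zs[perm_idx]])
        rho = spearman_rho(Zw, all_zs)
        rho[:, const_w] = 0.0
        signs = np.sign(rho)
        if count_scope == "significant_edges":
            p_two, _, _ = _rho_to_pvalues(rho, n)
            p_two[:, const_w] = 1.0
            in_scope = p_two < scope_p_threshold
        else:
            in_scope = np.ones_like(signs, dtype=bool)

    n_neg = np.sum((signs < 0) & in_scope, axis=1)
    n_pos = np.sum((signs > 0) & in_scope, axis=1)
    R = (n_neg + 1.0) / (n_pos + 1.0)
    observed_R = float(R[0])
    corrected_p = _corrected_p(R[1:], observed_R)
    obs_scope = int(in_scope[0].sum())
    if obs_scope == 0:
        warnings.warn("sign_bias_test: empty count scope; p set to 1", stacklevel=2)
        corrected_p = 1.0
    return SignBiasResult(
        n_neg=int(n_neg[0]),
        n_pos=int(n_pos[0]),
        ratio=observed_R,
        corrected_p=corrected_p,
        count_scope=count_scope,
        n_scope_edges=obs_scope,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def components_report(
    components: Sequence[ComponentResult], plan: PermutationPlan, extra: dict | None = None
) -> dict:
    report = {
        "plan": {
            "n_iterations": plan.n_iterations,
            "edge_p_threshold": plan.edge_p_threshold,
            "tail": plan.tail,
            "seed": plan.seed,
        },
        "components": [c.to_dict() for c in components],
    }
    if extra:
        report.update(extra)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def export_graphml(component: ComponentResult, path: str | Path) -> None:
    """Write one component as GraphML for external visualization."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(component.nodes)
    g.add_edges_from(component.edges)
    g.graph["corrected_p"] = (
        "" if component.corrected_p is None else float(component.corrected_p)
    )
    g.graph["tail"] = component.tail
    nx.write_graphml(g, str(path))
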