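"""Edge-wise nonparametric statistics over connectivity matrices.

Every unique connection of a layout (378 intra-hemispheric, 784 commissural,
1540 bilateral for 28 nodes per hemisphere) gets a Wilcoxon rank-sum group
comparison and/or a Spearman correlation with severity, each reported with
one- and two-tailed p-values, the sign of the effect, and the display
"sig-value" -log10(p_two) * sign.

Rank-sum p-values use midranks with the tie-corrected normal approximation;
when both groups have at most 5 subjects the exact permutation distribution
is enumerated instead (the normal approximation is poor there, and the small
problem makes full enumeration cheap).  The internal helpers are vectorized
over edges *and* over group-label permutations so that permutation inference
(see :mod:`speechconn.nbs`) can reuse them at scale: ranks depend only on the
data, so each permutation costs one matrix product.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .errors import ValidationError

_EXACT_MAX_GROUP = 5


# ---------------------------------------------------------------------------
# Vectorized rank-sum machinery (shared with permutation inference)
# ---------------------------------------------------------------------------

def _rank_columns(X: np.ndarray) -> np.ndarray:
    """Midranks of each column of the (subjects x edges) matrix."""
    return stats.rankdata(X, axis=0)


def _tie_terms(X: np.ndarray) -> np.ndarray:
    """Per-edge sum of t^3 - t over tied groups (0 when all values distinct)."""
    S, E = X.shape
    out = np.zeros(E)
    srt = np.sort(X, axis=0)
    has_ties = np.any(srt[1:] == srt[:-1], axis=0)
    for e in np.where(has_ties)[0]:
        _, counts = np.unique(X[:, e], return_counts=True)
        out[e] = float(np.sum(counts.astype(float) ** 3 - counts))
    return out


def ranksum_normal(
    ranks: np.ndarray, case_masks: np.ndarray, tie_terms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected normal-approximation z for case rank sums.

    ranks: (S, E) midranks; case_masks: (P, S) boolean label assignments (one
    row per permutation); tie_terms: (E,) from :func:`_tie_terms`.

    Returns (z, degenerate) each (P, E); ``degenerate`` marks edges whose
    null variance is zero (all subjects tied), where z is set to 0.
    """
    S = ranks.shape[0]
    n1 = case_masks[0].sum()
    n2 = S - n1
    W = case_masks.astype(float) @ ranks  # (P, E) case rank sums
    mu = n1 * (S + 1) / 2.0
    var = (n1 * n2 / 12.0) * ((S + 1) - tie_terms / (S * (S - 1)))
    degenerate = var <= 0
    sd = np.sqrt(np.where(degenerate, 1.0, var))
    z = (W - mu) / sd
    z[:, degenerate] = 0.0
    return z, np.broadcast_to(degenerate, z.shape)


def _z_to_pvalues(z: np.ndarray, degenerate: np.ndarray):
    """(p_two, p_one_neg, p_one_pos); the negative tail is case < control."""
    p_one_neg = stats.norm.cdf(z)
    p_one_pos = stats.norm.sf(z)
    p_two = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    for p in (p_one_neg, p_one_pos, p_two):
        p[degenerate] = 1.0
    return p_two, p_one_neg, p_one_pos


def _exact_ranksum(ranks: np.ndarray, case_mask: np.ndarray):
    """Exhaustive-permutation rank-sum p-values for one label assignment.

    Enumerates all C(S, n1) assignments of case labels; p's are tail counts
    of the case rank sum (ties with the observed sum included in both tails).
    Midranks are half-integers, so comparisons use doubled integer ranks.
    """
    S, E = ranks.shape
    n1 = int(case_mask.sum())
    r2 = np.rint(ranks * 2).astype(np.int64)
    combos = np.array(list(combinations(range(S), n1)))
    A = np.zeros((len(combos), S), dtype=np.int64)
    np.put_along_axis(A, combos, 1, axis=1)
    W_all = A @ r2  # (ncomb, E)
    W_obs = case_mask.astype(np.int64) @ r2  # (E,)
    p_le = (W_all <= W_obs[None, :]).mean(axis=0)
    p_ge = (W_all >= W_obs[None, :]).mean(axis=0)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    return p_two, p_le, p_ge


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------

def _standardize_columns(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columns centered/scaled to unit population variance; constants flagged."""
    mean = R.mean(axis=0)
    sd = R.std(axis=0)
    constant = sd <= 0
    Z = (R - mean) / np.where(constant, 1.0, sd)
    Z[:, constant] = 0.0
    return Z, constant


def spearman_rho(weight_ranks_std: np.ndarray, severity_ranks_std: np.ndarray) -> np.ndarray:
    """rho for (possibly many) standardized severity-rank vectors.

    weight_ranks_std: (S, E); severity_ranks_std: (P, S) (one row per
    permutation of the severity vector).  Returns (P, E).
    """
    S = weight_ranks_std.shape[0]
    return (severity_ranks_std @ weight_ranks_std) / S


def _rho_to_pvalues(rho: np.ndarray, n: int):
    """t-approximation p-values for Spearman rho; rho = +-1 clipped to p > 0."""
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho_c**2))
    p_one_neg = stats.t.cdf(t, df=n - 2)
    p_one_pos = stats.t.sf(t, df=n - 2)
    p_two = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    tiny = np.finfo(float).tiny
    return (
        np.maximum(tiny, p_two),
        np.maximum(tiny, p_one_neg),
        np.maximum(tiny, p_one_pos),
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def sig_value(p_two, sign):
    """Signed display statistic -log10(p_two) * sign; requires p in (0, 1]."""
    p = np.asarray(p_two, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("sig_value requires p-values in (0, 1]")
    out = -np.log10(p) * np.asarray(sign, dtype=float)
    return out if out.ndim else float(out)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (reject mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("fdr_bh requires p-values in (0, 1]")
    if not (0 < q < 1):
        raise ValidationError(f"q must be in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _table(
    node_i, node_j, statistic, sign, p_two, p_one_neg, p_one_pos
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_i": node_i,
            "node_j": node_j,
            "statistic": statistic,
            "sign": sign.astype(int),
            "p_two": p_two,
            "p_one_neg": p_one_neg,
            "p_one_pos": p_one_pos,
            "sig_value": -np.log10(p_two) * sign,
        }
    )


def ranksum_edges(cohort: Cohort, layout: str = "intra_left", exact: str = "auto") -> pd.DataFrame:
    """Per-edge Wilcoxon rank-sum comparison of case vs control weights.

    ``exact`` is "auto" (exhaustive enumeration when both groups <= 5),
    "always", or "never".  The sign column is the sign of
    mean(case) - mean(control).  Edges constant across all subjects get
    p = 1 and sign = 0.
    """
    cohort.require_groups()
    X, u, v, _ = cohort.edge_data(layout)
    case = cohort.case_mask
    n1, n2 = int(case.sum()), int((~case).sum())
    ranks = _rank_columns(X)

    mean_diff = X[case].mean(axis=0) - X[~case].mean(axis=0)
    sign = np.sign(mean_diff)

    use_exact = exact == "always" or (
        exact == "auto" and n1 <= _EXACT_MAX_GROUP and n2 <= _EXACT_MAX_GROUP
    )
    if exact not in ("auto", "always", "never"):
        raise ValidationError(f"exact must be auto/always/never, got {exact!r}")
    if use_exact:
        p_two, p_le, p_ge = _exact_ranksum(ranks, case)
        p_one_neg, p_one_pos = p_le, p_ge
        W = case.astype(float) @ ranks
        statistic = W
    else:
        tie = _tie_terms(X)
        z, degenerate = ranksum_normal(ranks, case[None, :], tie)
        p_two, p_one_neg, p_one_pos = (a[0] for a in _z_to_pvalues(z, degenerate))
        statistic = z[0]

    degenerate_edges = np.ptp(X, axis=0) == 0
    sign[degenerate_edges] = 0.0
    p_two = np.where(degenerate_edges, 1.0, p_two)
    p_one_neg = np.where(degenerate_edges, 1.0, p_one_neg)
    p_one_pos = np.where(degenerate_edges, 1.0, p_one_pos)

    li, lj = cohort.edge_labels(layout)
    return _table(li, lj, statistic, sign, p_two, p_one_neg, p_one_pos)


def spearman_edges(
    cohort: Cohort, layout: str = "intra_left", cases_only: bool = True
) -> pd.DataFrame:
    """Per-edge Spearman correlation between weights and severity scores.

    By default only case subjects enter (severity is a case-group construct);
    ``cases_only=False`` uses every subject with a severity score.  Edges
    with constant weights (or a constant severity vector) get rho = 0, p = 1.
    """
    X, u, v, _ = cohort.edge_data(layout)
    if cases_only:
        mask = cohort.require_severity()
    else:
        mask = ~np.isnan(cohort.severities)
        if int(mask.sum()) < 4:
            raise ValidationError("severity correlation needs >= 4 subjects with severity")
    Xs = X[mask]
    sev = cohort.severities[mask]
    n = Xs.shape[0]

    wr = _rank_columns(Xs)
    Zw, const_w = _standardize_columns(wr)
    sr = stats.rankdata(sev)
    Zs, const_s = _standardize_columns(sr[:, None])
    rho = spearman_rho(Zw, Zs.T)[0]

    undefined = const_w | bool(const_s[0])
    p_two, p_one_neg, p_one_pos = (a[0] for a in _rho_to_pvalues(rho[None, :], n))
    sign = np.sign(rho)
    sign[undefined] = 0.0
    rho = np.where(undefined, 0.0, rho)
    p_two = np.where(undefined, 1.0, p_two)
    p_one_neg = np.where(undefined, 1.0, p_one_neg)
    p_one_pos = np.where(undefined, 1.0, p_one_pos)

    li, lj = cohort.edge_labels(layout)
    return _table(li, lj, rho, sign, p_two, p_one_neg, p_one_pos)


def add_fdr(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Return a copy of an edge table with a BH-adjusted p column."""
    out = table.copy()
    _, out["fdr_adjusted_p"] = fdr_bh(out["p_two"].to_numpy(), q=q)
    return out


def write_edge_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
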