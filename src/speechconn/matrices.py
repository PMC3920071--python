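"""Connectivity matrices: normalization, symmetrization, bilateral assembly.

Edge weights are normalized tract densities: the mean probabilistic-streamline
density in a target ROI divided by the number of voxels in the seed ROI mask
(dimensionless).  Raw seed-to-target matrices are asymmetric because the
tract-tracing algorithm is directional even though diffusion itself is not;
the asymmetry is an algorithmic artifact, so intra-hemispheric matrices are
symmetrized as M = (M0 + M0^T) / 2.  Commissural (inter-hemispheric) matrices
are kept asymmetric for commissural-only analyses, and symmetrized the same
way only when embedded in the full bilateral matrix, which must be a valid
undirected graph.

Layouts
-------
``intra_left`` / ``intra_right``
    n x n square over one hemisphere's speech-network nodes; diagonal ignored.
``commissural``
    n x n with left-hemisphere seeds as rows and right-hemisphere targets as
    columns; may be asymmetric; all n^2 cells are distinct edges.
``bilateral``
    2n x 2n over both hemispheres (left block first), symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

INTRA_LAYOUTS = ("intra_left", "intra_right")
LAYOUTS = INTRA_LAYOUTS + ("commissural", "bilateral")

_SYM_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """One subject's nonnegative weighted connectivity matrix.

    ``row_labels``/``col_labels`` give the ordered node labels; they are equal
    for every layout except ``commissural`` (left seeds x right targets).
    """

    weights: np.ndarray
    row_labels: tuple[str, ...]
    layout: str
    symmetric: bool = False
    col_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.col_labels is None:
            self.col_labels = self.row_labels
        if self.layout not in LAYOUTS:
            raise ValidationError(f"unknown layout {self.layout!r}; expected one of {LAYOUTS}")
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"connectivity matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(self.row_labels) or w.shape[1] != len(self.col_labels):
            raise ValidationError(
                f"matrix shape {w.shape} does not match label counts "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValidationError(
                f"negative weight at ({self.row_labels[i]}, {self.col_labels[j]}): {w[i, j]}"
            )
        if self.layout != "commissural":
            np.fill_diagonal(self.weights, 0.0)  # self-connections never analyzed
        if self.symmetric and not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0):
            raise ValidationError(f"matrix marked symmetric but is not (layout {self.layout})")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.weights, index=list(self.row_labels), columns=list(self.col_labels))
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        layout: str,
        symmetric: bool = False,
        expected_row_labels: Sequence[str] | None = None,
        expected_col_labels: Sequence[str] | None = None,
    ) -> "ConnectivityMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except FileNotFoundError:
            raise ValidationError(f"matrix file not found: {path}") from None
        rows = tuple(str(x) for x in df.index)
        cols = tuple(str(x) for x in df.columns)
        for expected, got, which in (
            (expected_row_labels, rows, "row"),
            (expected_col_labels, cols, "column"),
        ):
            if expected is not None and tuple(expected) != got:
                raise ValidationError(
                    f"{path}: {which} labels do not match the parcellation "
                    f"(expected {list(expected)[:4]}..., got {list(got)[:4]}...)"
                )
        values = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(f"{path}: non-finite weight at cell ({rows[i]}, {cols[j]})")
        try:
            return cls(values, rows, layout, symmetric=symmetric, col_labels=cols)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Construction operations
# ---------------------------------------------------------------------------

def normalize_by_seed(
    raw_mean_densities: np.ndarray,
    seed_voxel_counts: Sequence[int],
    labels: Sequence[str],
    layout: str = "intra_left",
    col_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Divide each seed row of raw mean tract densities by its seed-mask size.

    Row i holds mean densities of tracts seeded at node i; entry (i, j)
    becomes raw(i, j) / seed_count(i).  The result is asymmetric.
    """
    raw = np.asarray(raw_mean_densities, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValidationError(f"raw density matrix must be square, got shape {raw.shape}")
    seeds = np.asarray(seed_voxel_counts, dtype=float)
    if seeds.shape != (raw.shape[0],):
        raise ValidationError(
            f"seed counts length {seeds.shape} does not match matrix size {raw.shape[0]}"
        )
    labels = tuple(labels)
    bad = np.where(seeds <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"seed voxel count must be positive; node {labels[bad[0]]!r} has {seeds[bad[0]]}"
        )
    if np.any(raw < 0):
        i, j = np.argwhere(raw < 0)[0]
        raise ValidationError(f"negative raw tract density at ({labels[i]}, {labels[j]})")
    normalized = raw / seeds[:, None]
    return ConnectivityMatrix(
        normalized,
        labels,
        layout,
        symmetric=False,
        col_labels=tuple(col_labels) if col_labels is not None else None,
    )


def symmetrize(m0: ConnectivityMatrix) -> ConnectivityMatrix:
    """Symmetric matrix M = (M0 + M0^T) / 2 with the diagonal zeroed.

    Only intra-hemispheric (and bilateral) matrices are symmetrized;
    commissural matrices stay asymmetric.
    """
    if m0.layout == "commissural":
        raise ValidationError("commissural matrices are asymmetric and must not be symmetrized")
    w = (m0.weights + m0.weights.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, m0.row_labels, m0.layout, symmetric=True)


def assemble_bilateral(
    left: ConnectivityMatrix,
    right: ConnectivityMatrix,
    commissural: ConnectivityMatrix,
) -> ConnectivityMatrix:
    """Combine two symmetric intra blocks and the commissural block into 2n x 2n.

    The commissural block C (left seeds x right targets) sits on the upper
    off-diagonal block as (C + C^T)/2 so the bilateral matrix is a valid
    undirected graph; the intra blocks are copied bit-identically.
    """
    if left.layout != "intra_left" or right.layout != "intra_right":
        raise ValidationError(
            f"expected intra_left and intra_right inputs, got {left.layout} and {right.layout}"
        )
    if commissural.layout != "commissural":
        raise ValidationError(f"third input must have commissural layout, got {commissural.layout}")
    if not (left.symmetric and right.symmetric):
        raise ValidationError("intra-hemispheric blocks must be symmetrized before assembly")
    n = left.n
    if right.n != n or commissural.n != n:
        raise ValidationError(
            f"block dimension mismatch: left {left.n}, right {right.n}, "
            f"commissural {commissural.n}"
        )
    csym = (commissural.weights + commissural.weights.T) / 2.0
    w = np.zeros((2 * n, 2 * n))
    w[:n, :n] = left.weights
    w[n:, n:] = right.weights
    w[:n, n:] = csym
    w[n:, :n] = csym.T
    labels = tuple(f"L.{lab}" for lab in left.row_labels) + tuple(
        f"R.{lab}" for lab in right.row_labels
    )
    return ConnectivityMatrix(w, labels, "bilateral", symmetric=True)


# ---------------------------------------------------------------------------
# Edge enumeration
# ---------------------------------------------------------------------------

def enumerate_edges(layout: str, n_per_hemisphere: int) -> int:
    """Number of unique connections in a layout over n nodes per hemisphere.

    intra: C(n, 2); commissural: n^2 (every left-right ordered pair is a
    distinct edge); bilateral: C(2n, 2) = 2*C(n, 2) + n^2.
    """
    n = int(n_per_hemisphere)
    if n < 2:
        raise ValidationError(f"need at least 2 nodes per hemisphere, got {n}")
    if layout in INTRA_LAYOUTS or layout == "intra":
        return n * (n - 1) // 2
    if layout == "commissural":
        return n * n
    if layout == "bilateral":
        return 2 * n * (2 * n - 1) // 2
    raise ValidationError(f"unknown layout {layout!r}")


def edge_index(layout: str, n: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Canonical unique-edge ordering for a layout.

    Returns (u, v, n_nodes) where u[k], v[k] are the node indices of edge k in
    the graph underlying the layout.  For intra and bilateral layouts these
    are the upper-triangle pairs of the n (or 2n) nodes.  For the commissural
    layout the graph is bipartite over 2n nodes (left 0..n-1, right n..2n-1)
    and the edges enumerate all n^2 (row, col) cells in row-major order.
    """
    if layout in INTRA_LAYOUTS or layout == "intra":
        u, v = np.triu_indices(n, k=1)
        return u, v, n
    if layout == "bilateral":
        u, v = np.triu_indices(n, k=1)  # here n is the full 2n node count
        return u, v, n
    if layout == "commissural":
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return i.ravel(), j.ravel() + n, 2 * n
    raise ValidationError(f"unknown layout {layout!r}")
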