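"""Cohort container: aligned subject matrices, group labels, severity scores.

A cohort couples one ``ConnectivityMatrix`` per subject per layout with a
subject table (id, group, optional severity).  Group labels are canonicalized
to ``case``/``control`` ("PWS"/"PFS" are accepted aliases).  All matrices in
a layout share one node order, so the cohort can expose a dense
(subjects x edges) view that the statistics modules operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import LAYOUTS, ConnectivityMatrix, edge_index

GROUP_ALIASES = {
    "case": "case",
    "control": "control",
    "pws": "case",
    "pfs": "control",
    "patient": "case",
}

_MANIFEST_MATRIX_COLUMNS = {
    "intra_left": "matrix_intra_left",
    "intra_right": "matrix_intra_right",
    "commissural": "matrix_commissural",
    "bilateral": "matrix_bilateral",
}


def canonical_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in GROUP_ALIASES:
        raise ValidationError(
            f"unknown group label {label!r}; expected case/control (or PWS/PFS)"
        )
    return GROUP_ALIASES[key]


@dataclass
class Subject:
    id: str
    group: str  # "case" | "control"
    severity: float | None = None

    def __post_init__(self) -> None:
        self.group = canonical_group(self.group)
        if self.severity is not None and np.isnan(self.severity):
            self.severity = None


@dataclass
class Cohort:
    """Aligned collection of per-subject connectivity matrices."""

    subjects: list[Subject]
    matrices: dict[str, list[ConnectivityMatrix]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.subjects)
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != n:
            raise ValidationError("duplicate subject ids in cohort")
        for layout, mats in self.matrices.items():
            if layout not in LAYOUTS:
                raise ValidationError(f"unknown layout {layout!r}")
            if len(mats) != n:
                raise ValidationError(
                    f"layout {layout}: {len(mats)} matrices for {n} subjects"
                )
            ref = mats[0]
            for subj, m in zip(self.subjects, mats):
                if m.row_labels != ref.row_labels or m.col_labels != ref.col_labels:
                    raise ValidationError(
                        f"subject {subj.id}: node labels differ from the rest of "
                        f"the cohort in layout {layout}"
                    )

    # ------------------------------------------------------------- accessors
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.group == "case" for s in self.subjects])

    @property
    def severities(self) -> np.ndarray:
        return np.array(
            [np.nan if s.severity is None else float(s.severity) for s in self.subjects]
        )

    def require_groups(self, min_size: int = 2) -> None:
        mask = self.case_mask
        n_case, n_control = int(mask.sum()), int((~mask).sum())
        if n_case < min_size or n_control < min_size:
            raise ValidationError(
                f"group comparison needs >= {min_size} subjects per group "
                f"(got {n_case} case, {n_control} control)"
            )

    def layout_labels(self, layout: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        mats = self._layout(layout)
        return mats[0].row_labels, mats[0].col_labels

    def _layout(self, layout: str) -> list[ConnectivityMatrix]:
        if layout not in self.matrices:
            raise ValidationError(
                f"cohort has no matrices for layout {layout!r} "
                f"(available: {sorted(self.matrices)})"
            )
        return self.matrices[layout]

    def edge_data(self, layout: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """Dense (subjects x unique-edges) weight matrix plus edge endpoints.

        Returns (X, u, v, n_nodes): X[s, k] is subject s's weight on edge k,
        whose graph endpoints are nodes u[k] and v[k].
        """
        mats = self._layout(layout)
        n = mats[0].n
        u, v, n_nodes = edge_index(layout, n)
        stack = np.stack([m.weights for m in mats])
        if layout == "commissural":
            X = stack.reshape(len(mats), -1)
        else:
            X = stack[:, u, v]
        return X, u, v, n_nodes

    def edge_labels(self, layout: str) -> tuple[np.ndarray, np.ndarray]:
        """Node-label pairs aligned with ``edge_data``'s edge ordering."""
        rows, cols = self.layout_labels(layout)
        n = len(rows)
        u, v, _ = edge_index(layout, n)
        if layout == "commissural":
            return (
                np.array([f"L.{rows[i]}" for i in u]),
                np.array([f"R.{cols[j - n]}" for j in v]),
            )
        labels = np.asarray(rows)
        return labels[u], labels[v]

    # ------------------------------------------------------------------ I/O
    def to_dir(self, directory: str | Path) -> Path:
        """Write matrices (TSV per subject per layout) and a manifest TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for k, subj in enumerate(self.subjects):
            row: dict[str, object] = {
                "subject_id": subj.id,
                "group": subj.group,
                "severity": "" if subj.severity is None else subj.severity,
            }
            for layout, mats in self.matrices.items():
                rel = f"{subj.id}_{layout}.tsv"
                mats[k].to_tsv(directory / rel)
                row[_MANIFEST_MATRIX_COLUMNS[layout]] = rel
            rows.append(row)
        manifest = directory / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        return manifest

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "Cohort":
        manifest_path = Path(manifest_path)
        if not manifest_path.exists():
            raise ValidationError(f"cohort manifest not found: {manifest_path}")
        df = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValidationError(f"{manifest_path}: manifest missing column {col!r}")
        base = manifest_path.parent
        layout_cols = {
            layout: col for layout, col in _MANIFEST_MATRIX_COLUMNS.items() if col in df.columns
        }
        if not layout_cols:
            raise ValidationError(f"{manifest_path}: no matrix path columns found")
        subjects: list[Subject] = []
        matrices: dict[str, list[ConnectivityMatrix]] = {layout: [] for layout in layout_cols}
        for _, row in df.iterrows():
            sev = row.get("severity")
            sev = None if sev is None or (isinstance(sev, float) and np.isnan(sev)) or sev == "" else float(sev)
            subj = Subject(id=str(row["subject_id"]), group=str(row["group"]), severity=sev)
            subjects.append(subj)
            for layout, col in layout_cols.items():
                path = base / str(row[col])
                if not path.exists():
                    raise ValidationError(
                        f"subject {subj.id}: matrix file missing for layout {layout}: {path}"
                    )
                m = ConnectivityMatrix.from_tsv(path, layout, symmetric=False)
                if layout != "commissural":
                    m.symmetric = bool(np.allclose(m.weights, m.weights.T, atol=1e-8, rtol=0))
                matrices[layout].append(m)
        return cls(subjects=subjects, matrices=matrices)

    def require_severity(self, min_n: int = 4) -> np.ndarray:
        """Case-subject mask with severity present; errors if too few."""
        mask = self.case_mask & ~np.isnan(self.severities)
        if int(mask.sum()) < min_n:
            missing = [
                s.id for s in self.subjects if s.group == "case" and s.severity is None
            ]
            raise ValidationError(
                f"severity correlation needs >= {min_n} case subjects with severity "
                f"scores (got {int(mask.sum())}; missing for {missing})"
            )
        return mask
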