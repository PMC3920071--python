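"""ROI-level aggregation of scalar volumes (e.g., FA) and per-ROI statistics.

Consumes a scalar value volume (fractional anisotropy, mean diffusivity, or
any other voxel-wise measure) together with an integer label volume of the
same shape assigning voxels to ROIs, and computes the arithmetic mean of the
values inside each label.  With 63 labels per hemisphere this yields 126
regional means per subject.  The module consumes label volumes; it does not
generate them (shallow-white-matter ROI construction is upstream anatomy
tooling).

Group statistics per ROI are classic two-tailed t-tests plus Pearson
correlation with severity among case subjects, reported uncorrected with an
optional Benjamini-Hochberg column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Subject
from .edgewise import fdr_bh
from .errors import ValidationError


@dataclass
class LabeledVolumePair:
    """A scalar 3-D volume plus an integer label volume of identical shape."""

    values: np.ndarray
    labels: np.ndarray
    label_table: dict[int, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape:
            raise ValidationError(
                f"value volume shape {self.values.shape} != label volume shape "
                f"{self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label volume must be integer-valued")
        names = list(self.label_table.values())
        if len(names) != len(set(names)):
            raise ValidationError("ROI names in the label table must be unique")


def load_volume(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume's data array."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)


def load_label_table(path: str | Path) -> dict[int, str]:
    """TSV with columns label_id, roi_name."""
    df = pd.read_csv(path, sep="\t")
    for col in ("label_id", "roi_name"):
        if col not in df.columns:
            raise ValidationError(f"{path}: label table missing column {col!r}")
    return {int(r.label_id): str(r.roi_name) for r in df.itertuples()}


def roi_means(pair: LabeledVolumePair, roi_ids=None) -> pd.DataFrame:
    """Mean value per ROI with voxel counts.

    ROIs with zero voxels are recorded with n_voxels = 0 and mean = NaN,
    with a warning.  Renumbering labels consistently in both the volume and
    the table leaves the (roi_name, mean) pairs unchanged.
    """
    if roi_ids is None:
        roi_ids = sorted(pair.label_table)
    rows = []
    flat_labels = pair.labels.ravel()
    flat_values = pair.values.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    sums = {}
    counts = {}
    # one pass over voxels grouped by label
    uniq, starts = np.unique(sorted_labels, return_index=True)
    bounds = list(starts) + [len(sorted_labels)]
    for k, lab in enumerate(uniq):
        seg = order[bounds[k]:bounds[k + 1]]
        sums[int(lab)] = float(flat_values[seg].sum())
        counts[int(lab)] = int(seg.size)
    for rid in roi_ids:
        rid = int(rid)
        if rid not in pair.label_table:
            raise ValidationError(f"ROI id {rid} not present in the label table")
        n_vox = counts.get(rid, 0)
        if n_vox == 0:
            warnings.warn(f"ROI {pair.label_table[rid]!r} (id {rid}) has no voxels", stacklevel=2)
            mean = np.nan
        else:
            mean = sums[rid] / n_vox
        rows.append(
            {"roi_id": rid, "roi": pair.label_table[rid], "n_voxels": n_vox, "mean": mean}
        )
    return pd.DataFrame(rows)


def roi_group_stats(
    per_subject: pd.DataFrame,
    subjects: list[Subject],
    with_fdr: bool = True,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI group comparison and severity correlation.

    ``per_subject`` is a long table with columns subject_id, roi, mean (one
    row per subject per ROI); every subject must cover the same ROI set.
    Output per ROI: group means, two-tailed t-test, sign and sig-value,
    Pearson correlation with severity over case subjects that have severity
    (with the count actually used), and an optional BH-adjusted p column.
    """
    for col in ("subject_id", "roi", "mean"):
        if col not in per_subject.columns:
            raise ValidationError(f"per-subject ROI table missing column {col!r}")
    wide = per_subject.pivot(index="subject_id", columns="roi", values="mean")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValidationError(
            f"subjects do not share the same ROI set (missing means for ROIs {bad[:5]})"
        )
    by_id = {s.id: s for s in subjects}
    missing = [i for i in wide.index if i not in by_id]
    if missing:
        raise ValidationError(f"ROI table contains unknown subjects: {missing[:5]}")
    is_case = np.array([by_id[i].group == "case" for i in wide.index])
    sev = np.array(
        [np.nan if by_id[i].severity is None else by_id[i].severity for i in wide.index],
        dtype=float,
    )
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValidationError("ROI group stats need >= 2 subjects per group")
    rows = []
    sev_mask = is_case & ~np.isnan(sev)
    for roi in wide.columns:
        vals = wide[roi].to_numpy()
        a, b = vals[is_case], vals[~is_case]
        t, p = stats.ttest_ind(a, b)
        if np.isnan(p):
            t, p = 0.0, 1.0
        sign = int(np.sign(a.mean() - b.mean()))
        if sev_mask.sum() >= 3 and np.ptp(vals[sev_mask]) > 0:
            r, p_r = stats.pearsonr(vals[sev_mask], sev[sev_mask])
        else:
            r, p_r = np.nan, np.nan
        rows.append(
            {
                "roi": roi,
                "mean_case": a.mean(),
                "mean_control": b.mean(),
                "t": t,
                "p_two": max(p, np.finfo(float).tiny),
                "sign": sign,
                "sig_value": -np.log10(max(p, np.finfo(float).tiny)) * sign,
                "severity_r": r,
                "severity_p": p_r,
                "n_severity": int(sev_mask.sum()),
            }
        )
    out = pd.DataFrame(rows)
    if with_fdr:
        _, out["fdr_adjusted_p"] = fdr_bh(out["p_two"].to_numpy(), q=q)
    return out
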