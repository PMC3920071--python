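"""Synthetic cohort generator for speech-network connectivity analyses.

The generator emulates the statistical structure the downstream inference
assumes, without simulating diffusion images or tractography mechanics:

* a shared group-mean baseline in which connection strength decays with the
  anterior-posterior distance between node order indices (local connections
  between nearby ROIs are the strongest, as in real tract-density matrices);
* multiplicative log-normal subject noise (tract densities are nonnegative
  and right-skewed), i.i.d. per subject and edge, with an optional
  per-subject global factor that induces correlation between edges;
* an optional planted group effect: a connected component of target edges
  whose case-group weights are scaled by a multiplier in (0, 1];
* optional severity structure: case severity scores drawn from
  13 + 33 * Beta(2, 2.5) (mimicking a clinical severity instrument with
  observed range 13-43 and median ~26), and a set of severity edges whose
  weights shrink multiplicatively with severity.

Default group sizes are 20 cases vs 17 controls, matching the cohort sizes
the analyses are calibrated for.  A single master seed drives everything;
per-subject streams are spawned deterministically from it, so identical
seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort, Subject
from .errors import ValidationError
from .matrices import ConnectivityMatrix, edge_index
from .parcellation import Parcellation

Edge = tuple[int, int]


@dataclass
class NoiseSpec:
    """Baseline construction and subject-level noise.

    baseline: "distance_decay" or "explicit".  Under distance decay the
    group-mean weight between nodes with order indices i and j is
    ``strength * exp(-|i - j| / scale)``.
    sigma: standard deviation of the per-edge log-normal noise.
    subject_sigma: sd of an extra per-subject global log-normal factor
    applied to every edge of that subject (0 disables it).
    """

    baseline: str = "distance_decay"
    strength: float = 1.0
    scale: float = 3.0
    sigma: float = 0.2
    subject_sigma: float = 0.0
    explicit_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.baseline not in ("distance_decay", "explicit"):
            raise ValidationError(f"unknown baseline kind {self.baseline!r}")
        if self.baseline == "distance_decay" and (self.strength <= 0 or self.scale <= 0):
            raise ValidationError(
                f"distance_decay needs strength > 0 and scale > 0 "
                f"(got {self.strength}, {self.scale})"
            )
        if self.sigma < 0 or self.subject_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")
        if self.baseline == "explicit" and self.explicit_matrix is None:
            raise ValidationError("explicit baseline requires explicit_matrix")


@dataclass
class EffectSpec:
    """Planted group and severity structure.

    target_edges: explicit edge list, or an integer k meaning "a random
    connected component of k edges" grown at simulation time.
    effect_multiplier: factor in (0, 1] applied to case-group weights on the
    target edges (1 = null).
    severity_edges: edge list (or integer k, as above) whose weights are
    multiplied by exp(severity_slope * (s - median(s))) per case subject.
    severity_slope: <= 0; per-unit-severity change of log weight.
    """

    target_edges: Sequence[Edge] | int | None = None
    effect_multiplier: float = 1.0
    severity_edges: Sequence[Edge] | int | None = None
    severity_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.effect_multiplier <= 1.0):
            raise ValidationError(
                f"effect_multiplier must be in (0, 1], got {self.effect_multiplier}"
            )
        if self.severity_slope > 0:
            raise ValidationError(f"severity_slope must be <= 0, got {self.severity_slope}")


def make_baseline(n_nodes: int, noise: NoiseSpec) -> np.ndarray:
    """Symmetric nonnegative group-mean matrix over ``n_nodes`` ordered nodes."""
    if noise.baseline == "explicit":
        base = np.asarray(noise.explicit_matrix, dtype=float)
        if base.shape != (n_nodes, n_nodes):
            raise ValidationError(
                f"explicit baseline shape {base.shape} != ({n_nodes}, {n_nodes})"
            )
        if np.any(base < 0):
            raise ValidationError("explicit baseline has negative weights")
        return base.copy()
    idx = np.arange(n_nodes)
    dist = np.abs(idx[:, None] - idx[None, :])
    base = noise.strength * np.exp(-dist / noise.scale)
    np.fill_diagonal(base, 0.0)
    return base


def random_connected_edges(n_nodes: int, n_edges: int, rng: np.random.Generator) -> list[Edge]:
    """Random set of ``n_edges`` edges forming one connected component.

    Grown as a random spanning tree over a fresh node each step, then padded
    with random extra edges inside the accumulated node set, so connectivity
    holds by construction.
    """
    max_nodes = min(n_nodes, n_edges + 1)
    if n_edges < 1:
        raise ValidationError("need at least one target edge")
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValidationError(f"cannot place {n_edges} unique edges on {n_nodes} nodes")
    nodes = list(rng.choice(n_nodes, size=max_nodes, replace=False))
    edges: set[Edge] = set()
    in_tree = [nodes[0]]
    for node in nodes[1:]:
        attach = in_tree[rng.integers(len(in_tree))]
        edges.add((min(attach, node), max(attach, node)))
        in_tree.append(node)
    while len(edges) < n_edges:
        a, b = rng.choice(in_tree, size=2, replace=False)
        edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def _resolve_edges(
    spec: Sequence[Edge] | int | None, n_nodes: int, rng: np.random.Generator
) -> list[Edge]:
    if spec is None:
        return []
    if isinstance(spec, (int, np.integer)):
        return random_connected_edges(n_nodes, int(spec), rng)
    edges = []
    for i, j in spec:
        i, j = int(i), int(j)
        if not (0 <= i < n_nodes and 0 <= j < n_nodes) or i == j:
            raise ValidationError(f"edge ({i}, {j}) is not a valid edge of a {n_nodes}-node layout")
        edges.append((min(i, j), max(i, j)))
    return sorted(set(edges))


def _edge_mask(edges: Sequence[Edge], n_nodes: int) -> np.ndarray:
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        mask[i, j] = mask[j, i] = True
    return mask


def simulate_cohort(
    parcellation: Parcellation | None = None,
    n_case: int = 20,
    n_control: int = 17,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    layouts: Sequence[str] = ("intra_left",),
    effect_layout: str = "intra_left",
) -> Cohort:
    """Simulate a two-group cohort of connectivity matrices.

    Per subject and edge: weight = baseline * exp(eps), eps ~ N(0, sigma^2)
    i.i.d.; case subjects additionally scaled by ``effect_multiplier`` on the
    target edges, and by exp(severity_slope * (s - median(s))) on the severity
    edges.  Intra-hemispheric matrices are exactly symmetric; commissural
    matrices get independent noise per (row, col) cell and stay asymmetric.
    """
    if parcellation is None:
        parcellation = Parcellation.default()
    if effect is None:
        effect = EffectSpec()
    if noise is None:
        noise = NoiseSpec()
    if n_case < 2 or n_control < 2:
        raise ValidationError(f"need >= 2 subjects per group (got {n_case}, {n_control})")
    for layout in layouts:
        if layout not in ("intra_left", "intra_right", "commissural", "bilateral"):
            raise ValidationError(f"unknown layout {layout!r}")
    if "bilateral" in layouts:
        needed = {"intra_left", "intra_right", "commissural"}
        layouts = tuple(dict.fromkeys(list(needed - set(layouts)) + list(layouts)))

    n = parcellation.n_speech_per_hemisphere
    ss = np.random.SeedSequence(int(seed))
    plant_ss, severity_ss, noise_ss = ss.spawn(3)
    plant_rng = np.random.default_rng(plant_ss)
    severity_rng = np.random.default_rng(severity_ss)

    # Effect geometry is resolved once, on the effect layout's node set.
    u, v, n_nodes_eff = edge_index(effect_layout, 2 * n if effect_layout == "bilateral" else n)
    target_edges = _resolve_edges(effect.target_edges, n_nodes_eff, plant_rng)
    severity_edges = _resolve_edges(effect.severity_edges, n_nodes_eff, plant_rng)

    base = make_baseline(n, noise)
    base_comm = make_baseline(n, noise)  # homotopic decay pattern for commissural block

    n_total = n_case + n_control
    groups = ["case"] * n_case + ["control"] * n_control
    severities_case = 13.0 + 33.0 * severity_rng.beta(2.0, 2.5, size=n_case)
    sev_center = float(np.median(severities_case))

    subject_streams = [np.random.default_rng(s) for s in noise_ss.spawn(n_total)]

    def noisy(rng: np.random.Generator, baseline: np.ndarray, symmetric: bool) -> np.ndarray:
        eps = rng.normal(0.0, noise.sigma, size=baseline.shape)
        if symmetric:
            eps = np.triu(eps, k=1)
            eps = eps + eps.T
        w = baseline * np.exp(eps)
        if noise.subject_sigma > 0:
            # one global factor per subject; drawn from the same stream
            w = w * np.exp(rng.normal(0.0, noise.subject_sigma))
        return w

    matrices: dict[str, list[ConnectivityMatrix]] = {layout: [] for layout in layouts}
    subjects: list[Subject] = []
    labels_left = parcellation.labels("left")
    labels_right = parcellation.labels("right")

    def apply_effects(w: np.ndarray, layout: str, is_case: bool, severity: float | None) -> None:
        if layout != effect_layout:
            return
        if layout == "commissural":
            # effect edges live on the bipartite 2n-node graph; map to cells
            def cells(edges: list[Edge]) -> tuple[np.ndarray, np.ndarray]:
                ii = np.array([min(a, b) for a, b in edges], dtype=int)
                jj = np.array([max(a, b) - n for a, b in edges], dtype=int)
                return ii, jj

            if is_case and target_edges:
                ii, jj = cells(target_edges)
                w[ii, jj] *= effect.effect_multiplier
            if is_case and severity_edges and severity is not None:
                ii, jj = cells(severity_edges)
                w[ii, jj] *= np.exp(effect.severity_slope * (severity - sev_center))
        else:
            if is_case and target_edges:
                m = _edge_mask(target_edges, w.shape[0])
                w[m] *= effect.effect_multiplier
            if is_case and severity_edges and severity is not None:
                m = _edge_mask(severity_edges, w.shape[0])
                w[m] *= np.exp(effect.severity_slope * (severity - sev_center))

    for k in range(n_total):
        is_case = groups[k] == "case"
        severity = float(severities_case[k]) if is_case else None
        subjects.append(Subject(id=f"sub{k:03d}", group=groups[k], severity=severity))
        rng = subject_streams[k]
        per_subject: dict[str, np.ndarray] = {}
        for layout in ("intra_left", "intra_right", "commissural"):
            if layout not in layouts:
                continue
            if layout == "commissural":
                w = noisy(rng, base_comm, symmetric=False)
            else:
                w = noisy(rng, base, symmetric=True)
            apply_effects(w, layout, is_case, severity)
            per_subject[layout] = w
        for layout in layouts:
            if layout == "bilateral":
                continue
            w = per_subject[layout]
            if layout == "commissural":
                cm = ConnectivityMatrix(
                    w,
                    tuple(labels_left),
                    "commissural",
                    symmetric=False,
                    col_labels=tuple(labels_right),
                )
            else:
                lbl = labels_left if layout == "intra_left" else labels_right
                cm = ConnectivityMatrix(w, tuple(lbl), layout, symmetric=True)
            matrices[layout].append(cm)
        if "bilateral" in layouts:
            from .matrices import assemble_bilateral

            bil = assemble_bilateral(
                matrices["intra_left"][-1],
                matrices["intra_right"][-1],
                matrices["commissural"][-1],
            )
            if effect_layout == "bilateral":
                w = bil.weights
                apply_effects(w, "bilateral", is_case, severity)
                w = (w + w.T) / 2.0
                bil = ConnectivityMatrix(w, bil.row_labels, "bilateral", symmetric=True)
            matrices["bilateral"].append(bil)

    return Cohort(
        subjects=subjects,
        matrices=matrices,
        meta={
            "seed": int(seed),
            "target_edges": [list(e) for e in target_edges],
            "severity_edges": [list(e) for e in severity_edges],
            "effect_multiplier": effect.effect_multiplier,
            "severity_slope": effect.severity_slope,
            "sigma": noise.sigma,
            "subject_sigma": noise.subject_sigma,
            "effect_layout": effect_layout,
        },
    )
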