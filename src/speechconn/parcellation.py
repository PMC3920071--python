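"""Cortical parcellation model for the speech network.

A parcellation is an ordered list of nodes (cortical ROIs), each tagged with a
hemisphere, a fixed order index (lobe-major, anterior-to-posterior within
lobe), and a flag marking membership in the speech-production network.  The
node order is part of the analysis contract: every subject's connectivity
matrix in a run is defined over the same ordered node list, so edge indices
are comparable across subjects.

The default speech-network label list (28 ROIs per hemisphere) is a
best-effort reconstruction from the ROI names used in the speech-motor
literature (ventral/middle/dorsal motor and premotor subdivisions, SMA and
pre-SMA, opercular and insular regions, supramarginal and superior temporal
subdivisions).  The exact published membership is not restated anywhere in
machine-readable form, so the list is user-overridable via YAML/JSON configs
and should be replaced with the study-specific list for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ValidationError

HEMISPHERES = ("left", "right")

#: Default speech-network ROI labels for one hemisphere, ordered lobe-major
#: and anterior-to-posterior (frontal, then parietal, then insular/opercular,
#: then temporal).  Best-effort reconstruction; override for real studies.
SPEECH_NETWORK_LABELS: tuple[str, ...] = (
    # frontal: inferior frontal, opercular, premotor, medial, primary motor
    "vIFo", "dIFo", "aFO", "pFO", "aINS",
    "vPMC", "midPMC", "pdPMC", "preSMA", "SMA",
    "vMC", "midMC", "dMC",
    # parietal: somatosensory, supramarginal, parietal operculum
    "vSC", "dSC", "aSMg", "pSMg", "PO",
    # posterior insula and central operculum
    "pINS", "aCO", "pCO",
    # temporal: Heschl's, planum polare/temporale, superior temporal
    "Hg", "PP", "PT", "aSTg", "pSTg", "adSTs", "pdSTs",
)


@dataclass(frozen=True)
class Node:
    """One parcellation ROI."""

    label: str
    hemisphere: str
    index: int
    speech_network: bool = True

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"node {self.label!r}: hemisphere must be one of {HEMISPHERES}, "
                f"got {self.hemisphere!r}"
            )


class Parcellation:
    """Ordered node list shared by all subjects in an analysis run.

    Nodes are stored hemisphere-major (all left nodes first, then all right
    nodes), each hemisphere ordered by the node ``index`` field.
    """

    def __init__(self, nodes: Iterable[Node]):
        nodes = list(nodes)
        if not nodes:
            raise ValidationError("parcellation must contain at least one node")
        for hemi in HEMISPHERES:
            labels = [n.label for n in nodes if n.hemisphere == hemi]
            if len(labels) != len(set(labels)):
                dup = sorted({x for x in labels if labels.count(x) > 1})
                raise ValidationError(
                    f"duplicate node labels in {hemi} hemisphere: {dup}"
                )
        self.nodes: tuple[Node, ...] = tuple(
            sorted(nodes, key=lambda n: (HEMISPHERES.index(n.hemisphere), n.index))
        )

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parcellation) and self.nodes == other.nodes

    def hemisphere_nodes(self, hemisphere: str, speech_only: bool = True) -> tuple[Node, ...]:
        if hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {hemisphere!r}")
        return tuple(
            n
            for n in self.nodes
            if n.hemisphere == hemisphere and (n.speech_network or not speech_only)
        )

    def labels(self, hemisphere: str, speech_only: bool = True) -> tuple[str, ...]:
        return tuple(n.label for n in self.hemisphere_nodes(hemisphere, speech_only))

    def bilateral_labels(self, speech_only: bool = True) -> tuple[str, ...]:
        """Hemisphere-qualified labels, left hemisphere first."""
        return tuple(
            f"{hemi[0].upper()}.{lab}"
            for hemi in HEMISPHERES
            for lab in self.labels(hemi, speech_only)
        )

    @property
    def n_speech_per_hemisphere(self) -> int:
        n_left = len(self.hemisphere_nodes("left"))
        n_right = len(self.hemisphere_nodes("right"))
        if n_left != n_right:
            raise ValidationError(
                f"speech-network node counts differ between hemispheres "
                f"({n_left} left vs {n_right} right)"
            )
        return n_left

    # ------------------------------------------------------------------ I/O
    @classmethod
    def default(cls, labels: Sequence[str] = SPEECH_NETWORK_LABELS) -> "Parcellation":
        """Bilateral speech-network parcellation with the default 28 labels."""
        nodes = [
            Node(label=lab, hemisphere=hemi, index=i, speech_network=True)
            for hemi in HEMISPHERES
            for i, lab in enumerate(labels)
        ]
        return cls(nodes)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "nodes": [
                {
                    "label": n.label,
                    "hemisphere": n.hemisphere,
                    "index": n.index,
                    "speech_network": n.speech_network,
                }
                for n in self.nodes
            ]
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Parcellation":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "nodes" not in data:
            raise ValidationError(f"{path}: parcellation file must contain a 'nodes' list")
        nodes = []
        for i, entry in enumerate(data["nodes"]):
            try:
                nodes.append(
                    Node(
                        label=str(entry["label"]),
                        hemisphere=str(entry["hemisphere"]),
                        index=int(entry.get("index", i)),
                        speech_network=bool(entry.get("speech_network", True)),
                    )
                )
            except KeyError as exc:
                raise ValidationError(f"{path}: node entry {i} missing field {exc}") from exc
        return cls(nodes)
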