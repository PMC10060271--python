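"""Frame-to-frame organoid tracking with fusion events.

Organoids in embedded culture are near-static, so tracking is greedy and
overlap-based: each object in frame t links to the frame-t+1 object its
pixels overlap most. When two or more frame-t objects map onto one
frame-t+1 object, that is a merge (fusion) event; objects with no
overlap partner generate appearance or disappearance events. There is no
motion model and no splitting — organoids do not divide at object level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .config import ValidationError
from .segmentation import LabeledMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackNode:
    frame: int
    label: int
    centroid: tuple[float, float]
    area_px: int


@dataclass
class TrackGraph:
    """Object instances, frame-to-frame links, and merge/appear/disappear events."""

    nodes: list[TrackNode] = field(default_factory=list)
    edges: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    merges: list[dict] = field(default_factory=list)
    appearances: list[tuple[int, int]] = field(default_factory=list)
    disappearances: list[tuple[int, int]] = field(default_factory=list)

    def count_per_frame(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for n in self.nodes:
            counts[n.frame] = counts.get(n.frame, 0) + 1
        return counts

    def successors(self, frame: int, label: int) -> list[tuple[int, int]]:
        return [dst for src, dst in self.edges if src == (frame, label)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": [
                {"frame": n.frame, "label": n.label, "centroid": list(n.centroid),
                 "area_px": n.area_px}
                for n in self.nodes
            ],
            "edges": [[list(a), list(b)] for a, b in self.edges],
            "merges": self.merges,
            "appearances": [list(a) for a in self.appearances],
            "disappearances": [list(a) for a in self.disappearances],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _nodes_of(mask: LabeledMask, frame: int) -> list[TrackNode]:
    ids = mask.label_ids
    if len(ids) == 0:
        return []
    centroids = ndi.center_of_mass(mask.labels > 0, mask.labels, ids)
    areas = mask.areas_px()
    return [
        TrackNode(frame=frame, label=int(k), centroid=(float(c[0]), float(c[1])),
                  area_px=areas[int(k)])
        for k, c in zip(ids, centroids)
    ]


def track_objects(masks: list[LabeledMask]) -> TrackGraph:
    """Link labeled masks across consecutive frames by maximal pixel overlap.

    Ties between candidate successors resolve to the largest-overlap
    partner, then larger predecessor area, then lower label. A frame-t+1
    object claimed by >= 2 predecessors records one merge event at t+1.
    """
    if not masks:
        raise ValidationError("masks: at least one frame required")
    shapes = {m.labels.shape for m in masks}
    if len(shapes) != 1:
        raise ValidationError(f"masks: frames must share dimensions, got {shapes}")

    graph = TrackGraph()
    for t, m in enumerate(masks):
        graph.nodes.extend(_nodes_of(m, t))
    if len(masks) == 1:
        logger.warning("track_objects: single frame, empty edge set")
        return graph

    for label in masks[0].label_ids:
        graph.appearances.append((0, int(label)))

    for t in range(len(masks) - 1):
        a, b = masks[t], masks[t + 1]
        areas_a = a.areas_px()
        # joint histogram of (label_t, label_t+1) over co-foreground pixels
        both = (a.labels > 0) & (b.labels > 0)
        la, lb = a.labels[both], b.labels[both]
        max_b = int(b.labels.max()) + 1
        joint = np.zeros((int(a.labels.max()) + 1, max_b), dtype=np.int64)
        np.add.at(joint, (la, lb), 1)

        claimed: dict[int, list[tuple[int, int]]] = {}  # succ -> [(pred, overlap)]
        matched_b: set[int] = set()
        for ka in a.label_ids:
            row = joint[ka]
            if row.sum() == 0:
                graph.disappearances.append((t, int(ka)))
                continue
            best = np.flatnonzero(row == row.max())
            kb = int(best[0])  # lowest successor label on ties
            graph.edges.append(((t, int(ka)), (t + 1, kb)))
            claimed.setdefault(kb, []).append((int(ka), int(row[kb])))
            matched_b.add(kb)
        for kb, preds in claimed.items():
            if len(preds) >= 2:
                preds_sorted = sorted(
                    preds, key=lambda p: (-areas_a[p[0]], p[0])
                )
                graph.merges.append(
                    {"frame": t + 1, "successor": kb,
                     "predecessors": [p[0] for p in preds_sorted]}
                )
        for kb in b.label_ids:
            if int(kb) not in matched_b:
                graph.appearances.append((t + 1, int(kb)))
    return graph
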