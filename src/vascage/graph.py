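"""Spatial vessel-centerline graphs.

A :class:`VesselGraph` stores the centerline geometry of a vascular network:
nodes are branch points and endpoints (positions in µm), and each edge carries
an ordered centerline polyline with a per-point radius estimate.  It is the
substrate for every structural metric in :mod:`vascage.metrics` and the output
of both the synthetic generator and the volume-tracing pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

COMPARTMENTS = ("artery", "capillary", "vein", "unknown")


@dataclass
class VesselEdge:
    """One vessel segment between two graph nodes.

    Parameters
    ----------
    node_a, node_b
        Node ids of the two endpoints.
    polyline
        ``(n, 3)`` ordered centerline points in µm.  The first and last points
        must coincide with the positions of ``node_a`` and ``node_b``.
    radii
        Per-point radius in µm, same length as ``polyline``; strictly positive.
    compartment
        Vessel compartment tag, one of ``artery | capillary | vein | unknown``.
    """

    node_a: int
    node_b: int
    polyline: np.ndarray
    radii: np.ndarray
    compartment: str = "unknown"

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 3:
            raise ValueError("polyline must be an (n, 3) array")
        if self.polyline.shape[0] < 2:
            raise ValueError("polyline needs at least two points")
        if self.radii.shape != (self.polyline.shape[0],):
            raise ValueError("radii must match polyline length")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be strictly positive")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.arc_length() == 0:
            raise ValueError("zero-length edge")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)

    def arc_length(self) -> float:
        """Centerline path length (µm), summed over Euclidean steps."""
        return float(self.segment_lengths().sum())

    def chord_length(self) -> float:
        """Straight-line distance between the two endpoints (µm)."""
        return float(np.linalg.norm(self.polyline[-1] - self.polyline[0]))

    def mean_radius(self) -> float:
        """Length-weighted mean radius along the edge (µm)."""
        seg = self.segment_lengths()
        mid_r = 0.5 * (self.radii[:-1] + self.radii[1:])
        return float(np.average(mid_r, weights=seg))


@dataclass
class VesselGraph:
    """Vessel centerline network: nodes (µm positions) plus polyline edges."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    edges: list[VesselEdge] = field(default_factory=list)

    def add_node(self, position) -> int:
        nid = len(self.nodes)
        while nid in self.nodes:
            nid += 1
        self.nodes[nid] = np.asarray(position, dtype=float)
        return nid

    def add_edge(self, edge: VesselEdge) -> None:
        for nid, end in ((edge.node_a, edge.polyline[0]), (edge.node_b, edge.polyline[-1])):
            if nid not in self.nodes:
                raise KeyError(f"edge references unknown node {nid}")
            if not np.allclose(self.nodes[nid], end, atol=1e-6):
                raise ValueError(f"polyline endpoint does not match node {nid} position")
        self.edges.append(edge)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[int, int]:
        deg = {nid: 0 for nid in self.nodes}
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return deg

    def branch_nodes(self) -> list[int]:
        """Node ids with degree >= 3 (junctions)."""
        return [nid for nid, d in self.degrees().items() if d >= 3]

    def total_length(self) -> float:
        """Total centerline length over all edges (µm)."""
        return float(sum(e.arc_length() for e in self.edges))

    def mean_radius(self) -> float:
        """Length-weighted mean radius over the whole graph (µm)."""
        if not self.edges:
            return 0.0
        lengths = np.array([e.arc_length() for e in self.edges])
        radii = np.array([e.mean_radius() for e in self.edges])
        return float(np.average(radii, weights=lengths))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([e.polyline for e in self.edges]) if self.edges else np.zeros((1, 3))
        return pts.min(axis=0), pts.max(axis=0)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": {str(k): v.tolist() for k, v in self.nodes.items()},
            "edges": [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "polyline": e.polyline.tolist(),
                    "radii": e.radii.tolist(),
                    "compartment": e.compartment,
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselGraph":
        g = cls(nodes={int(k): np.asarray(v, dtype=float) for k, v in d["nodes"].items()})
        for ed in d["edges"]:
            g.edges.append(
                VesselEdge(
                    node_a=int(ed["node_a"]),
                    node_b=int(ed["node_b"]),
                    polyline=np.asarray(ed["polyline"], dtype=float),
                    radii=np.asarray(ed["radii"], dtype=float),
                    compartment=ed.get("compartment", "unknown"),
                )
            )
        return g

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "VesselGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))


def merge_passthrough_nodes(graph: VesselGraph) -> None:
    """Join edge pairs meeting at degree-2 nodes into single edges, in place.

    Used after pruning operations that can leave former junctions with only
    two incident edges (the graph invariant keeps degree-2 nodes only as
    explicit endpoints of closed loops).
    """
    while True:
        deg = graph.degrees()
        target = None
        for nid, d in deg.items():
            if d == 2:
                inc = [e for e in graph.edges if nid in (e.node_a, e.node_b)]
                if len(inc) == 2 and inc[0] is not inc[1]:
                    target = (nid, inc)
                    break
        if target is None:
            return
        nid, (e1, e2) = target

        def oriented(e: VesselEdge, end_at: int):
            if e.node_b == end_at:
                return e.polyline, e.radii, e.node_a
            return e.polyline[::-1], e.radii[::-1], e.node_b

        p1, r1, start = oriented(e1, nid)
        p2, r2, _ = oriented(e2, nid)
        end = e2.node_b if e2.node_a == nid else e2.node_a
        poly = np.vstack([p1, p2[::-1][1:]])
        radii = np.concatenate([r1, r2[::-1][1:]])
        graph.edges = [e for e in graph.edges if e is not e1 and e is not e2]
        graph.edges.append(VesselEdge(start, end, poly, radii))


def prune_terminal_stubs(graph: VesselGraph, min_length_um: float) -> None:
    """Remove terminal edges shorter than ``min_length_um`` that hang off a
    junction, then absorb any degree-2 nodes left behind.  In place."""
    changed = True
    while changed:
        changed = False
        deg = graph.degrees()
        keep = []
        for e in graph.edges:
            is_stub = (deg[e.node_a] == 1 or deg[e.node_b] == 1) and (
                deg[e.node_a] >= 3 or deg[e.node_b] >= 3
            )
            if is_stub and e.arc_length() < min_length_um:
                changed = True
            else:
                keep.append(e)
        graph.edges = keep
    merge_passthrough_nodes(graph)
    used = {e.node_a for e in graph.edges} | {e.node_b for e in graph.edges}
    graph.nodes = {nid: pos for nid, pos in graph.nodes.items() if nid in used}


def arc_chord_ratio(polyline: np.ndarray) -> float:
    """Tortuosity of a centerline as arc length over chord length.

    The arc length is the sum of Euclidean step lengths along the polyline and
    the chord is the straight-line distance between its first and last points.
    A straight vessel gives 1.0; tortuous vessels give values > 1.

    Raises
    ------
    ValueError
        If the polyline has fewer than two distinct points or its endpoints
        coincide (closed loop: the chord is zero and the ratio undefined).
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must contain at least two points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if chord <= 1e-9 * max(arc, 1.0):
        raise ValueError("chord length is zero (closed loop); arc-chord ratio undefined")
    return arc / chord
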