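"""Centerline extraction and fly-through camera paths for virtual endoscopy.

The intraluminal view itself is delegated to whatever renderer the user
prefers; this module produces its geometric substrate — a skeleton graph of
the segmented lumen (root at the renal pelvis, one tip per calyx) and
resampled camera waypoints with view directions along a root→tip path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .segmentation import SegmentationMask
from .volume_io import CTVolume, LabelVolume, voxel_to_world, world_to_voxel


class EndoscopyError(ValueError):
    pass


@dataclass
class CenterlineGraph:
    """Skeleton graph of the lumen: nodes are mm positions, edges carry
    physical length; roles are root / tip / branch / internal."""

    graph: nx.Graph
    root: tuple[int, int, int]

    @property
    def tips(self) -> list[tuple[int, int, int]]:
        return [n for n in self.graph.nodes
                if self.graph.degree(n) == 1 and n != self.root]

    def role(self, node) -> str:
        if node == self.root:
            return "root"
        deg = self.graph.degree(node)
        if deg == 1:
            return "tip"
        if deg >= 3:
            return "branch"
        return "internal"

    def position_mm(self, node) -> np.ndarray:
        return np.asarray(self.graph.nodes[node]["position_mm"])

    def path_length_mm(self, a, b) -> float:
        return float(nx.shortest_path_length(self.graph, a, b, weight="length"))


@dataclass
class Waypoint:
    position_mm: tuple[float, float, float]
    direction: tuple[float, float, float]


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def _skeleton_graph(skel: np.ndarray, vol) -> nx.Graph:
    """26-connected voxel graph over skeleton voxels, edge weight = mm length."""
    g = nx.Graph()
    pts = np.argwhere(skel)
    voxset = set(map(tuple, pts))
    spacing = np.asarray(vol.spacing)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for p in map(tuple, pts):
        g.add_node(p, position_mm=tuple(voxel_to_world(vol, p)))
        for off in offsets:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in voxset:
                g.add_edge(p, q, length=float(np.linalg.norm(np.asarray(off) * spacing)))
    return g


def _prune_spurs(g: nx.Graph, keep: tuple, min_length_mm: float) -> None:
    """Iteratively remove leaf branches shorter than ``min_length_mm``."""
    changed = True
    while changed and g.number_of_nodes() > 1:
        changed = False
        for tip in [n for n in g.nodes if g.degree(n) == 1 and n != keep]:
            path = [tip]
            length = 0.0
            node = tip
            while g.degree(node) <= 2:
                nbrs = [n for n in g.neighbors(node) if n not in path]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["length"]
                if g.degree(nxt) >= 3 or length >= min_length_mm:
                    break
                path.append(nxt)
                node = nxt
            if length < min_length_mm and keep not in path:
                g.remove_nodes_from(path)
                changed = True


def extract_centerline(mask, vol: CTVolume | LabelVolume,
                       prune_spur_mm: float = 2.0) -> CenterlineGraph:
    """Skeletonize the lumen mask into a centerline graph.

    The mask must be one connected component; spurs shorter than
    ``prune_spur_mm`` (skeletonization noise at default voxel sizes) are
    pruned; the root is the skeleton voxel with the largest inscribed-sphere
    radius, which for a PCS is inside the renal pelvis.
    """
    m = _mask_array(mask)
    if not m.any():
        raise EndoscopyError("empty mask")
    n_comp = ndi.label(m, structure=np.ones((3, 3, 3), bool))[1]
    if n_comp != 1:
        raise EndoscopyError(f"mask must be a single connected component (got {n_comp})")
    skel = skeletonize(m)
    if not skel.any():
        # a compact blob skeletonizes to nothing: represent it by its
        # innermost voxel as a single-node graph
        edt = ndi.distance_transform_edt(m, sampling=vol.spacing)
        idx = np.unravel_index(int(np.argmax(edt)), edt.shape)
        skel = np.zeros_like(m)
        skel[idx] = True
    g = _skeleton_graph(skel, vol)
    if g.number_of_nodes() == 0:
        raise EndoscopyError("degenerate lumen: skeleton is empty")
    # root = maximal inscribed sphere
    edt = ndi.distance_transform_edt(m, sampling=vol.spacing)
    if g.number_of_nodes() > 1 and all(
            g.degree(n) == g.number_of_nodes() - 1 for n in g.nodes):
        # mutually adjacent voxel clique: a compact blob with no elongation —
        # collapse to its innermost voxel
        nodes = list(g.nodes)
        best = nodes[int(np.argmax([edt[n] for n in nodes]))]
        g = nx.Graph()
        g.add_node(best, position_mm=tuple(voxel_to_world(vol, best)))
    nodes = list(g.nodes)
    radii = [edt[n] for n in nodes]
    root = nodes[int(np.argmax(radii))]
    _prune_spurs(g, keep=root, min_length_mm=prune_spur_mm)
    if root not in g:
        raise EndoscopyError("degenerate lumen: root pruned")
    # keep the component containing the root (pruning cannot split, but be safe)
    comp = nx.node_connected_component(g, root)
    g = g.subgraph(comp).copy()
    return CenterlineGraph(graph=g, root=root)


def flythrough_path(graph: CenterlineGraph, target_tip,
                    step_mm: float = 1.0) -> list[Waypoint]:
    """Camera waypoints along the root→tip centerline path.

    Positions are resampled at ``step_mm`` arc-length intervals; the view
    direction at each waypoint is the local path tangent (unit vector,
    (z, y, x) components in mm space).
    """
    if graph.role(target_tip) != "tip":
        raise EndoscopyError("target must be a tip node")
    nodes = nx.shortest_path(graph.graph, graph.root, target_tip, weight="length")
    pos = np.array([graph.position_mm(n) for n in nodes])
    if len(pos) == 1:
        raise EndoscopyError("degenerate path: root equals tip")
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    n_steps = max(int(np.floor(total / step_mm)), 1)
    samples = np.linspace(0.0, total, n_steps + 1)
    resampled = np.column_stack([np.interp(samples, s, pos[:, i]) for i in range(3)])
    tangents = np.gradient(resampled, samples, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents = tangents / norms
    return [Waypoint(tuple(p), tuple(t)) for p, t in zip(resampled, tangents)]


def waypoints_to_json(waypoints: list[Waypoint]) -> str:
    return json.dumps([{"position_mm": list(w.position_mm),
                        "direction": list(w.direction)} for w in waypoints], indent=2)
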