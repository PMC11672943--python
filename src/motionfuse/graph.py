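"""Skeleton graph layouts and partitioned adjacency for graph convolution.

The subject is a seated child filmed from above the screen, so the layout
covers the head and upper body only: 9 head keypoints (nose, eyes, ears,
mouth corners, head top, neck) and 8 upper-body keypoints (shoulders,
elbows, wrists, hips), 17 joints in total.

Two edge layouts are supported:

* ``"new"`` — the plain anatomical skeleton (a tree rooted at the neck).
* ``"our"`` — the anatomical skeleton plus four behaviour-motivated edges:
  nose-to-both-shoulders (head movement relative to the torso) and
  hip-to-same-side-mouth-corner (shortens the face/body topological
  distance, helping with sway detection).

For convolution the adjacency is split into the standard three spatial
subsets — self, centripetal (neighbour closer to the centre joint) and
centrifugal (neighbour farther) — each degree-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "JOINT_NAMES", "SkeletonGraph", "AdjacencyStack",
    "build_graph", "partition_adjacency",
]

JOINT_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_mouth", "right_mouth", "head_top", "neck",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
)

# anatomical tree: child -> parent; the neck is the root / centre joint
_PARENTS = {
    "nose": "neck",
    "left_eye": "nose", "right_eye": "nose",
    "left_ear": "left_eye", "right_ear": "right_eye",
    "left_mouth": "nose", "right_mouth": "nose",
    "head_top": "nose",
    "left_shoulder": "neck", "right_shoulder": "neck",
    "left_elbow": "left_shoulder", "right_elbow": "right_shoulder",
    "left_wrist": "left_elbow", "right_wrist": "right_elbow",
    "left_hip": "neck", "right_hip": "neck",
}

_EXTRA_EDGES = (
    ("nose", "left_shoulder"), ("nose", "right_shoulder"),
    ("left_hip", "left_mouth"), ("right_hip", "right_mouth"),
)

#: Hip-to-mouth interpretation: one edge per side (2 edges). The all-pairs
#: alternative (each hip to both mouth corners) is available via
#: ``build_graph("our", mouth_edges="all_pairs")``.
_EXTRA_EDGES_ALL_PAIRS = (
    ("nose", "left_shoulder"), ("nose", "right_shoulder"),
    ("left_hip", "left_mouth"), ("left_hip", "right_mouth"),
    ("right_hip", "left_mouth"), ("right_hip", "right_mouth"),
)


@dataclass(frozen=True)
class SkeletonGraph:
    """A vertex layout with an undirected edge set and a parent map."""

    joints: tuple = JOINT_NAMES
    edges: frozenset = field(default_factory=frozenset)  # of frozenset pairs (indices)
    parents: dict = field(default_factory=dict)          # joint index -> parent index
    variant: str = "our"
    center: str = "neck"

    @property
    def num_joints(self) -> int:
        return len(self.joints)

    def index(self, name: str) -> int:
        return self.joints.index(name)

    @property
    def center_index(self) -> int:
        return self.index(self.center)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency (no self loops)."""
        V = self.num_joints
        A = np.zeros((V, V))
        for e in self.edges:
            i, j = tuple(e)
            A[i, j] = A[j, i] = 1.0
        return A

    def degree(self, name: str) -> int:
        i = self.index(name)
        return int(self.adjacency()[i].sum())

    def hop_distance_to_center(self) -> np.ndarray:
        """BFS hop count from every vertex to the centre joint."""
        V = self.num_joints
        A = self.adjacency()
        dist = np.full(V, -1, dtype=int)
        dist[self.center_index] = 0
        frontier = [self.center_index]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for v in frontier:
                for w in np.nonzero(A[v])[0]:
                    if dist[w] < 0:
                        dist[w] = d
                        nxt.append(int(w))
            frontier = nxt
        return dist

    # -- serialization --------------------------------------------------
    def to_yaml(self, path):
        doc = {
            "joints": list(self.joints),
            "edges": sorted(sorted(self.joints[i] for i in e) for e in self.edges),
            "parents": {self.joints[c]: self.joints[p] for c, p in self.parents.items()},
            "variant": self.variant,
            "center": self.center,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SkeletonGraph":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        joints = tuple(doc["joints"])
        idx = {n: i for i, n in enumerate(joints)}
        edges = frozenset(frozenset((idx[a], idx[b])) for a, b in doc["edges"])
        parents = {idx[c]: idx[p] for c, p in doc["parents"].items()}
        return cls(joints=joints, edges=edges, parents=parents,
                   variant=doc.get("variant", "custom"), center=doc.get("center", "neck"))


def build_graph(variant: str = "our", mouth_edges: str = "per_side") -> SkeletonGraph:
    """Build one of the two 17-joint layouts.

    Parameters
    ----------
    variant:
        ``"new"`` for the plain anatomical skeleton, ``"our"`` for the
        augmented layout with nose-shoulder and hip-mouth edges.
    mouth_edges:
        ``"per_side"`` (default, 2 hip-mouth edges) or ``"all_pairs"``
        (4 hip-mouth edges) for the augmented layout.
    """
    idx = {n: i for i, n in enumerate(JOINT_NAMES)}
    tree = frozenset(frozenset((idx[c], idx[p])) for c, p in _PARENTS.items())
    if variant == "new":
        edges = tree
    elif variant == "our":
        if mouth_edges == "per_side":
            extra = _EXTRA_EDGES
        elif mouth_edges == "all_pairs":
            extra = _EXTRA_EDGES_ALL_PAIRS
        else:
            raise ValueError(f"unknown mouth_edges option: {mouth_edges!r}")
        edges = tree | frozenset(frozenset((idx[a], idx[b])) for a, b in extra)
    else:
        raise ValueError(f"unknown graph variant: {variant!r} (expected 'our' or 'new')")
    parents = {idx[c]: idx[p] for c, p in _PARENTS.items()}
    return SkeletonGraph(edges=edges, parents=parents, variant=variant)


@dataclass(frozen=True)
class AdjacencyStack:
    """K_v degree-normalized adjacency subsets, shape (K_v, V, V)."""

    subsets: np.ndarray
    variant: str = "our"

    @property
    def num_subsets(self) -> int:
        return self.subsets.shape[0]

    @property
    def num_joints(self) -> int:
        return self.subsets.shape[1]


def _degree_normalize(A: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Column-normalize: A @ diag(1 / (column degree + eps)).

    Zero-degree columns (vertices isolated within a subset) stay zero.
    """
    deg = A.sum(axis=0)
    return A / np.where(deg > 0, deg + eps, 1.0)


def partition_adjacency(graph: SkeletonGraph, eps: float = 1e-4) -> AdjacencyStack:
    """Spatial-configuration partition into self/centripetal/centrifugal.

    Entry ``A_k[v, w]`` is nonzero when vertex ``w`` aggregates from
    neighbour ``v`` in subset ``k`` (so features are applied as
    ``x @ A_k``).  Neighbours at equal hop distance to the centre are
    assigned to the self/root subset, following the usual convention.
    """
    V = graph.num_joints
    A = graph.adjacency()
    dist = graph.hop_distance_to_center()
    self_loop = np.eye(V)
    centripetal = np.zeros((V, V))
    centrifugal = np.zeros((V, V))
    for w in range(V):
        for v in np.nonzero(A[:, w])[0]:
            if dist[v] < dist[w]:
                centripetal[v, w] = 1.0
            elif dist[v] > dist[w]:
                centrifugal[v, w] = 1.0
            else:
                self_loop[v, w] = 1.0
    subsets = np.stack([
        _degree_normalize(self_loop, eps),
        _degree_normalize(centripetal, eps),
        _degree_normalize(centrifugal, eps),
    ]).astype(np.float32)
    return AdjacencyStack(subsets=subsets, variant=graph.variant)
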