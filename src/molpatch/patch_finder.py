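"""Largest-hydrophobic-patch detection on surface point clouds.

Surface points within the edge cutoff (default 1.25 A) of each other are
connected; only edges whose two endpoints are both hydrophobic are kept,
which partitions the hydrophobic surface into isolated patches (connected
components).  Patches are ranked by area; the rank-1 area is the LHP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import StructureModel
from .surface import PointCloud, SurfaceParams, compute_point_cloud


@dataclass
class Patch:
    """One connected hydrophobic surface component."""

    point_indices: np.ndarray          # indices into the full cloud
    area: float                        # sum of member point weights, A^2
    residues: frozenset[int]           # owning residue indices
    rank: int = 0                      # 1 = largest area


@dataclass
class PatchSet:
    patches: list[Patch]
    params: SurfaceParams

    @property
    def lhp_area(self) -> float:
        return self.patches[0].area if self.patches else 0.0

    def __len__(self) -> int:
        return len(self.patches)


def build_edges(cloud: PointCloud, cutoff: float) -> list[tuple[int, int]]:
    """All point pairs (i, j), i < j, within Euclidean distance ``cutoff``.

    Matches a brute-force all-pairs enumeration (distance <= cutoff).
    """
    if cloud.n_points == 0:
        raise ValueError("empty point cloud")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(cloud.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return [(int(i), int(j)) for i, j in np.sort(pairs, axis=1)]


def hydrophobic_subgraph(
    cloud: PointCloud, edges: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Retain only edges whose both endpoints are hydrophobic points."""
    flags = cloud.hydrophobic
    return [(i, j) for i, j in edges if flags[i] and flags[j]]


def find_patches(cloud: PointCloud, params: SurfaceParams | None = None) -> PatchSet:
    """Extract hydrophobic patches as connected components, ranked by area.

    Isolated hydrophobic points count as singleton patches, so patch areas
    always partition the total hydrophobic surface area exactly.  Ties in
    area are broken by the smallest member residue index, then the smallest
    member point index, for deterministic ranking.
    """
    params = params or cloud.params
    hydro_idx = np.flatnonzero(cloud.hydrophobic)
    if hydro_idx.size == 0:
        return PatchSet(patches=[], params=params)

    coords = cloud.coords[hydro_idx]
    # Edges among hydrophobic points only: identical to building all edges
    # and then dropping any edge with a hydrophilic endpoint.
    tree = cKDTree(coords)
    pairs = tree.query_pairs(params.effective_cutoff(), output_type="ndarray")

    n = hydro_idx.size
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n), dtype=np.int8)
    n_comp, labels = connected_components(adj, directed=False)

    patches: list[Patch] = []
    for c in range(n_comp):
        members_local = np.flatnonzero(labels == c)
        members = hydro_idx[members_local]
        area = float(cloud.area_weight[members].sum())
        residues = frozenset(int(r) for r in np.unique(cloud.owner_residue[members]))
        patches.append(Patch(point_indices=members, area=area, residues=residues))

    patches.sort(
        key=lambda p: (-p.area, min(p.residues), int(p.point_indices.min()))
    )
    for rank, p in enumerate(patches, start=1):
        p.rank = rank
    return PatchSet(patches=patches, params=params)


def lhp(model: StructureModel, params: SurfaceParams | None = None) -> float:
    """Largest hydrophobic patch area (A^2) for a structure model."""
    params = params or SurfaceParams()
    cloud = compute_point_cloud(model, params)
    return find_patches(cloud, params).lhp_area
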