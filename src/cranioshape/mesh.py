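"""Corresponded triangle meshes, region partitions, and displacement fields.

All meshes handled here are assumed to be in dense point correspondence with a
shared template: identical vertex count and identical triangulation, so that
vertex ``i`` has the same anatomical meaning in every mesh.  Correspondence is
established upstream (registration is external preprocessing and is never
re-computed here); this module only *validates* the topological contract and
refuses meshes that break it.

Mesh I/O supports ASCII PLY and Wavefront OBJ.  Files are written with
double-precision coordinates so that a write/read round trip is lossless to
well below 1e-6 mm; reading goes through :mod:`trimesh` with processing
disabled to preserve vertex order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import connected_components, dijkstra


class CorrespondenceError(ValueError):
    """A mesh does not match its template's topology."""


@dataclass
class CorrespondedMesh:
    """Triangle mesh in dense correspondence with a template.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in millimetres.
    faces : (M, 3) int array
        Triangles as 0-based vertex-index triples. The face list is shared
        verbatim with the template.
    template_id : str
        Identifier of the correspondence template.
    """

    vertices: np.ndarray
    faces: np.ndarray
    template_id: str = "template"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) array")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(
            self.vertices
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.vertices)))

    def validate(self) -> None:
        """Check structural invariants (finiteness, full vertex usage,
        connectedness)."""
        if not self.is_finite():
            raise ValueError("mesh has non-finite vertex coordinates")
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.faces.ravel()] = True
        if not used.all():
            raise ValueError("mesh has vertices not referenced by any face")
        n_comp, _ = connected_components(
            vertex_adjacency(self.faces, self.n_vertices), directed=False
        )
        if n_comp != 1:
            raise ValueError(f"mesh surface is disconnected ({n_comp} components)")

    def with_vertices(self, vertices: np.ndarray) -> "CorrespondedMesh":
        """Copy sharing topology but with new coordinates."""
        return CorrespondedMesh(
            np.asarray(vertices, dtype=float), self.faces, self.template_id
        )

    def copy(self) -> "CorrespondedMesh":
        return CorrespondedMesh(
            self.vertices.copy(), self.faces, self.template_id
        )


@dataclass
class RegionPartition:
    """Per-vertex assignment of anatomic-subunit labels.

    ``labels[i]`` is the 1-based region id of vertex ``i``;
    ``region_names[r - 1]`` names region ``r``.
    """

    labels: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        n_regions = int(self.labels.max(initial=0))
        if not self.region_names:
            self.region_names = [f"region_{r:02d}" for r in range(1, n_regions + 1)]
        if len(self.region_names) != n_regions:
            raise ValueError("region_names length must equal the number of regions")
        if self.labels.min(initial=1) < 1:
            raise ValueError("region ids must be 1-based positive integers")
        if n_regions < 2:
            raise ValueError("a partition needs at least 2 regions")
        counts = np.bincount(self.labels, minlength=n_regions + 1)[1:]
        if (counts == 0).any():
            empty = [r + 1 for r in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty regions: {empty}")

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_name(self, r: int) -> str:
        return self.region_names[r - 1]


@dataclass
class Template:
    """Correspondence template: reference mesh plus its region partition."""

    mesh: CorrespondedMesh
    partition: RegionPartition

    def __post_init__(self) -> None:
        if self.partition.n_vertices != self.mesh.n_vertices:
            raise ValueError(
                "partition length does not match template vertex count"
            )

    @property
    def template_id(self) -> str:
        return self.mesh.template_id

    @property
    def n_regions(self) -> int:
        return self.partition.n_regions


# ---------------------------------------------------------------------------
# topology helpers


def vertex_adjacency(faces: np.ndarray, n_vertices: int) -> sp.csr_matrix:
    """Boolean vertex-adjacency matrix of the triangulation's edge graph."""
    f = np.asarray(faces)
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    data = np.ones(len(rows), dtype=np.int8)
    adj = sp.coo_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices))
    adj = adj.tocsr()
    adj.data[:] = 1
    return adj


def graph_distance_from_set(
    adj: sp.csr_matrix, vertex_set: np.ndarray
) -> np.ndarray:
    """Hop distance of every vertex from the given vertex set (0 inside)."""
    idx = np.asarray(list(vertex_set), dtype=int)
    dist = dijkstra(adj, directed=False, unweighted=True, indices=idx, min_only=True)
    return dist


def blend_weights(
    adj: sp.csr_matrix, vertex_set: np.ndarray, n_vertices: int, rings: int = 2
) -> np.ndarray:
    """Smooth 0..1 weight field: 1 on the set, linear falloff over ``rings``
    hops outside it, 0 beyond."""
    dist = graph_distance_from_set(adj, vertex_set)
    w = np.clip(1.0 - dist / (rings + 1.0), 0.0, 1.0)
    return w


# ---------------------------------------------------------------------------
# operations


def validate_against_template(
    mesh: CorrespondedMesh, template: Template
) -> None:
    """Raise :class:`CorrespondenceError` unless ``mesh`` shares the
    template's exact topology."""
    t = template.mesh
    if mesh.n_vertices != t.n_vertices:
        raise CorrespondenceError(
            f"vertex count {mesh.n_vertices} != template {t.n_vertices}: "
            "dense correspondence is broken"
        )
    if mesh.faces.shape != t.faces.shape or not np.array_equal(mesh.faces, t.faces):
        raise CorrespondenceError("face list differs from the template's")
    if not mesh.is_finite():
        raise ValueError("mesh has non-finite vertex coordinates")


def read_mesh(path: str | os.PathLike, template: Template) -> CorrespondedMesh:
    """Read a PLY or OBJ mesh and validate it against the template.

    The returned mesh uses the template's face list and template id; only the
    coordinates are taken from the file (the file's triangulation must match).
    """
    loaded = trimesh.load(str(path), process=False, maintain_order=True)
    if not hasattr(loaded, "vertices"):
        raise ValueError(f"could not parse a triangle mesh from {path}")
    mesh = CorrespondedMesh(
        np.asarray(loaded.vertices, dtype=float),
        np.asarray(loaded.faces, dtype=np.int64),
        template.template_id,
    )
    validate_against_template(mesh, template)
    return mesh


def write_mesh(
    mesh: CorrespondedMesh, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a mesh as ASCII PLY or OBJ with double-precision coordinates."""
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower()
    if format not in ("ply", "obj"):
        raise ValueError(f"unsupported mesh format: {format!r}")
    if not mesh.is_finite():
        raise ValueError("refusing to write mesh with non-finite coordinates")
    with open(path, "w") as f:
        if format == "ply":
            f.write(
                "ply\nformat ascii 1.0\n"
                f"comment template {mesh.template_id}\n"
                f"element vertex {mesh.n_vertices}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {mesh.n_faces}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for v in mesh.vertices:
                f.write("%.17g %.17g %.17g\n" % (v[0], v[1], v[2]))
            for fc in mesh.faces:
                f.write("3 %d %d %d\n" % (fc[0], fc[1], fc[2]))
        else:
            f.write(f"# template {mesh.template_id}\n")
            for v in mesh.vertices:
                f.write("v %.17g %.17g %.17g\n" % (v[0], v[1], v[2]))
            for fc in mesh.faces:  # OBJ indices are 1-based
                f.write("f %d %d %d\n" % (fc[0] + 1, fc[1] + 1, fc[2] + 1))


def vertex_displacements(
    pre: CorrespondedMesh, post: CorrespondedMesh
) -> np.ndarray:
    """Per-vertex Euclidean displacement (mm) between two corresponded meshes."""
    if pre.template_id != post.template_id:
        raise CorrespondenceError("meshes are on different templates")
    if pre.n_vertices != post.n_vertices:
        raise CorrespondenceError("vertex counts differ")
    return np.linalg.norm(post.vertices - pre.vertices, axis=1)


def region_vertices(partition: RegionPartition, r: int) -> np.ndarray:
    """Sorted 0-based vertex indices belonging to region ``r`` (1-based)."""
    if not 1 <= r <= partition.n_regions:
        raise ValueError(f"unknown region id {r} (valid: 1..{partition.n_regions})")
    return np.flatnonzero(partition.labels == r)


# ---------------------------------------------------------------------------
# partition sidecar I/O (CSV: vertex_index, region_id, region_name)


def write_partition(partition: RegionPartition, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "vertex_index": np.arange(partition.n_vertices),
            "region_id": partition.labels,
            "region_name": [
                partition.region_name(r) for r in partition.labels
            ],
        }
    )
    df.to_csv(path, index=False)


def read_partition(path: str | os.PathLike) -> RegionPartition:
    df = pd.read_csv(path).sort_values("vertex_index")
    labels = df["region_id"].to_numpy()
    names: dict[int, str] = {}
    for rid, name in zip(df["region_id"], df["region_name"]):
        names[int(rid)] = str(name)
    region_names = [names[r] for r in sorted(names)]
    return RegionPartition(labels, region_names)
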