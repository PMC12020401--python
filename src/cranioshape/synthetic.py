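"""Synthetic corresponded head-mesh populations with known ground truth.

Real cohorts of syndromic craniosynostosis are small, private, and reach the
latent analysis only after external registration; this module builds their
stand-in: a head-like closed surface template partitioned into anatomic
subunits, populations of healthy and syndromic subjects whose class identity
is a region-localized smooth shape offset, and simulated midfacial surgery
that moves chosen regions toward (or away from) the healthy mean with a known
completeness ``alpha``.  Every generator is a pure function of its spec,
including the seed.

Shape variation model
---------------------
Smooth displacement fields are spanned by low-order polynomial harmonics of
the template's radial directions (constant + degree-1 + degree-2 terms, nine
basis functions per coordinate channel).  Class offsets are such fields
confined to designated regions with a one-ring smooth falloff; within-class
individual variation is a low-rank Gaussian combination of a few shared
smooth modes, scaled to a per-vertex RMS of ``individual_sd`` millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import dijkstra

from cranioshape.latent import LatentLayout
from cranioshape.mesh import (
    CorrespondedMesh,
    RegionPartition,
    Template,
    blend_weights,
    region_vertices,
    vertex_adjacency,
)

#: Nominal anatomic-subunit names used for the default 15-region template.
#: The synthetic partition is geometric (geodesic cells), so the names are
#: labels of convenience, not anatomically registered patches.
DEFAULT_REGION_NAMES = [
    "frontal",
    "supraorbital",
    "left_orbit",
    "right_orbit",
    "nose",
    "central_midface",
    "left_cheek",
    "right_cheek",
    "upper_lip",
    "nasolabial",
    "chin",
    "left_ear",
    "right_ear",
    "cranial_vault",
    "occiput",
]

#: Approximate semi-axes of a head (mm): left-right, front-back, up-down.
HEAD_SEMI_AXES = (75.0, 95.0, 110.0)


# ---------------------------------------------------------------------------
# template construction


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly equally spaced unit directions (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_template(
    n_subdivisions: int = 4,
    seed: int = 0,
    n_regions: int = 15,
    region_names: list[str] | None = None,
) -> Template:
    """Build the synthetic head template and its region partition.

    The surface is a subdivided icosphere (``10 * 4**n + 2`` vertices)
    anisotropically scaled to head proportions, with a nose-like protrusion on
    the facial side.  The partition grows ``n_regions`` contiguous geodesic
    cells from fixed anchor directions; edge lengths are jittered with the
    seeded RNG so region boundaries are organic rather than great circles.
    """
    if n_subdivisions < 1:
        raise ValueError("n_subdivisions must be >= 1")
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=n_subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float)  # unit directions
    faces = np.asarray(ico.faces, dtype=np.int64)

    # nose-like radial protrusion on the facial (+y) side, below the equator
    nose_dir = np.array([0.0, 1.0, -0.15])
    nose_dir /= np.linalg.norm(nose_dir)
    ang = np.arccos(np.clip(u @ nose_dir, -1.0, 1.0))
    bump = 0.22 * np.exp(-((ang / 0.35) ** 2))
    radial = 1.0 + bump
    vertices = u * radial[:, None] * np.array(HEAD_SEMI_AXES)

    template_id = f"synthhead-sub{n_subdivisions}-r{n_regions}-seed{seed}"
    mesh = CorrespondedMesh(vertices, faces, template_id)

    # seeded geodesic growing from fixed anchor directions
    anchors_dir = _fibonacci_directions(n_regions)
    anchor_idx = np.array([int(np.argmax(u @ d)) for d in anchors_dir])
    if len(set(anchor_idx.tolist())) != n_regions:
        raise ValueError("anchor directions collide; mesh too coarse for R")
    edges = mesh_edges(faces)
    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    jitter = 1.0 + 0.5 * rng.random(len(edges))
    w = lengths * jitter
    n = len(vertices)
    adj_w = sp.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    _, _, sources = dijkstra(
        adj_w, directed=False, indices=anchor_idx, min_only=True,
        return_predecessors=True,
    )
    # sources holds the anchor vertex id that reached each vertex first;
    # label propagation along shortest paths keeps every cell contiguous
    src_to_region = {int(v): k + 1 for k, v in enumerate(anchor_idx)}
    labels = np.array([src_to_region[int(s)] for s in sources], dtype=np.int64)

    if region_names is None:
        if n_regions == len(DEFAULT_REGION_NAMES):
            region_names = list(DEFAULT_REGION_NAMES)
        else:
            region_names = [f"region_{r:02d}" for r in range(1, n_regions + 1)]
    partition = RegionPartition(labels, region_names)
    return Template(mesh, partition)


def mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges of a triangulation."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


# ---------------------------------------------------------------------------
# smooth fields


def harmonic_basis(template: Template) -> np.ndarray:
    """N x 9 matrix of low-order polynomial harmonics of the radial
    directions, columns normalized to unit per-vertex RMS."""
    u = template.mesh.vertices / np.linalg.norm(
        template.mesh.vertices, axis=1, keepdims=True
    )
    x, y, z = u.T
    cols = [
        np.ones_like(x), x, y, z,
        x * y, x * z, y * z, x**2 - y**2, 3.0 * z**2 - 1.0,
    ]
    B = np.column_stack(cols)
    B /= np.sqrt((B**2).mean(axis=0))
    return B


def smooth_field(
    template: Template, coeffs: np.ndarray, basis: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate a smooth (N, 3) displacement field from 9 x 3 coefficients."""
    if basis is None:
        basis = harmonic_basis(template)
    coeffs = np.asarray(coeffs, dtype=float).reshape(basis.shape[1], 3)
    return basis @ coeffs


def region_offset_field(
    template: Template,
    r: int,
    effect_mm: float,
    rng: np.random.Generator,
    basis: np.ndarray | None = None,
    adj: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Smooth displacement field confined to region ``r`` with a one-ring
    falloff, scaled so its RMS magnitude over the region is ``effect_mm``."""
    if adj is None:
        adj = vertex_adjacency(template.mesh.faces, template.mesh.n_vertices)
    if basis is None:
        basis = harmonic_basis(template)
    coeffs = rng.normal(size=(basis.shape[1], 3))
    f = basis @ coeffs
    idx = region_vertices(template.partition, r)
    # squared one-ring falloff keeps >=90% of the field energy inside the
    # designated region while still tapering smoothly at the boundary
    w = blend_weights(adj, idx, template.mesh.n_vertices, rings=1) ** 2
    f = f * w[:, None]
    rms = np.sqrt((f[idx] ** 2).sum(axis=1).mean())
    if rms < 1e-12:
        raise ValueError("degenerate offset field")
    return f * (effect_mm / rms)


# ---------------------------------------------------------------------------
# populations


@dataclass
class PopulationSpec:
    """Study conditions for a synthetic three-class cohort.

    ``region_effects`` maps class name -> {region id: effect size (mm)}; the
    healthy class carries no offset by convention.  ``individual_sd`` is the
    per-vertex RMS magnitude (mm) of within-class variation, realized as a
    Gaussian combination of ``n_modes`` shared smooth fields.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"healthy": 30, "synA": 30, "synB": 30}
    )
    region_effects: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "healthy": {},
            "synA": {6: 10.0, 5: 8.0, 9: 8.0},
            "synB": {6: 8.0, 2: 8.0, 1: 10.0},
        }
    )
    individual_sd: float = 1.0
    n_modes: int = 3
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("n_per_class entries must be >= 1")
        if self.individual_sd < 0 or self.n_modes < 1:
            raise ValueError("invalid variation parameters")
        for cls, eff in self.region_effects.items():
            for r, e in eff.items():
                if not np.isfinite(e):
                    raise ValueError(f"non-finite effect for {cls} region {r}")
        if self.region_effects.get("healthy"):
            raise ValueError("healthy class must have zero class offset")


@dataclass
class SyntheticSubject:
    """One generated subject: mesh plus the ground truth that made it."""

    subject_id: str
    class_label: str
    mesh: CorrespondedMesh
    truth: dict = field(default_factory=dict)
    stage: str = "pre"
    augmented: bool = False


def class_offset_fields(
    spec: PopulationSpec, template: Template
) -> dict[str, np.ndarray]:
    """Deterministic per-class offset fields implied by the spec."""
    basis = harmonic_basis(template)
    adj = vertex_adjacency(template.mesh.faces, template.mesh.n_vertices)
    offsets: dict[str, np.ndarray] = {}
    for ci, cls in enumerate(sorted(spec.region_effects)):
        off = np.zeros((template.mesh.n_vertices, 3))
        for r, eff in sorted(spec.region_effects[cls].items()):
            rng = np.random.default_rng([spec.seed, 7919, ci, r])
            off += region_offset_field(template, r, eff, rng, basis, adj)
        offsets[cls] = off
    return offsets


def sample_population(
    spec: PopulationSpec,
    template: Template,
    draw_seed: int | None = None,
    id_prefix: str = "",
) -> list[SyntheticSubject]:
    """Draw the cohort: template + class offset + low-rank individual field.

    The population *structure* (class offset fields, shared variation modes)
    is a function of ``spec.seed`` alone; ``draw_seed`` re-seeds only the
    individual draws, so held-out subjects sampled with a different
    ``draw_seed`` come from the same distribution as the training cohort.
    """
    spec.validate()
    basis = harmonic_basis(template)
    offsets = class_offset_fields(spec, template)
    # shared individual-variation modes, unit per-vertex RMS each
    mode_rng = np.random.default_rng([spec.seed, 104729])
    modes = []
    for _ in range(spec.n_modes):
        g = basis @ mode_rng.normal(size=(basis.shape[1], 3))
        g /= np.sqrt((g**2).sum(axis=1).mean())
        modes.append(g)
    subjects = []
    draw = spec.seed if draw_seed is None else draw_seed
    for cls in sorted(spec.n_per_class):
        n = spec.n_per_class[cls]
        rng = np.random.default_rng([draw, 15485863, hash_label(cls)])
        off = offsets.get(cls, np.zeros_like(template.mesh.vertices))
        for i in range(n):
            a = rng.normal(size=spec.n_modes)
            indiv = sum(
                a[j] * modes[j] for j in range(spec.n_modes)
            ) * (spec.individual_sd / np.sqrt(spec.n_modes))
            v = template.mesh.vertices + off + indiv
            mesh = CorrespondedMesh(v, template.mesh.faces, template.template_id)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{cls}_{id_prefix}{i:03d}",
                    class_label=cls,
                    mesh=mesh,
                    truth={
                        "region_effects": dict(spec.region_effects.get(cls, {})),
                        "mode_coeffs": a.tolist(),
                    },
                )
            )
    return subjects


def hash_label(label: str) -> int:
    """Stable small non-negative integer from a class label."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def class_mean_mesh(
    subjects: Iterable[SyntheticSubject], class_label: str
) -> CorrespondedMesh:
    """Vertex-wise mean mesh of one class."""
    meshes = [s.mesh for s in subjects if s.class_label == class_label]
    if not meshes:
        raise ValueError(f"no subjects of class {class_label!r}")
    v = np.mean([m.vertices for m in meshes], axis=0)
    return meshes[0].with_vertices(v)


# ---------------------------------------------------------------------------
# surgery


@dataclass
class SurgerySpec:
    """Simulated intervention on a set of regions.

    ``completeness`` alpha scales the movement along the subject-to-healthy
    difference: 0 leaves the shape unchanged, 1 removes the regional deviation
    entirely, values above 1 overcorrect past the healthy mean.
    """

    target_regions: tuple[int, ...]
    completeness: float = 1.0
    direction_mode: str = "toward_healthy"
    noise_sd: float = 0.0
    procedure_label: str = "procedure"
    seed: int = 0

    def validate(self) -> None:
        if not self.target_regions:
            raise ValueError("target_regions must be non-empty")
        if self.completeness < 0:
            raise ValueError("completeness must be >= 0")
        if self.direction_mode not in (
            "toward_healthy", "away_from_healthy", "random"
        ):
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def apply_surgery(
    subject: SyntheticSubject,
    spec: SurgerySpec,
    healthy_mean_mesh: CorrespondedMesh,
    template: Template,
) -> SyntheticSubject:
    """Produce the postoperative subject.

    On target regions the vertices move by ``alpha`` times the difference to
    the healthy mean (sign per ``direction_mode``); a one-ring blend outside
    the target set avoids seams; optional smooth residual noise of per-vertex
    RMS ``noise_sd`` mm is added under the same blend weights.
    """
    spec.validate()
    if subject.mesh.template_id != healthy_mean_mesh.template_id:
        raise ValueError("healthy mean mesh is on a different template")
    adj = vertex_adjacency(template.mesh.faces, template.mesh.n_vertices)
    target = np.concatenate(
        [region_vertices(template.partition, r) for r in spec.target_regions]
    )
    w = blend_weights(adj, target, template.mesh.n_vertices, rings=1)
    v = subject.mesh.vertices
    diff = healthy_mean_mesh.vertices - v
    alpha = spec.completeness
    if spec.direction_mode == "toward_healthy":
        move = alpha * diff
    elif spec.direction_mode == "away_from_healthy":
        move = -alpha * diff
    else:  # random smooth field of matched norm on the target set
        rng = np.random.default_rng([spec.seed, 999983])
        g = smooth_field(template, rng.normal(size=(9, 3)))
        g_norm = np.sqrt((g[target] ** 2).sum())
        ref_norm = np.sqrt(((alpha * diff[target]) ** 2).sum())
        move = g * (ref_norm / max(g_norm, 1e-12))
    post = v + w[:, None] * move
    if spec.noise_sd > 0:
        rng_n = np.random.default_rng([spec.seed, 613651, hash_label(subject.subject_id)])
        noise = smooth_field(template, rng_n.normal(size=(9, 3)))
        noise *= spec.noise_sd / np.sqrt((noise**2).sum(axis=1).mean())
        post = post + w[:, None] * noise
    truth = dict(subject.truth)
    truth["surgery"] = {
        "completeness": alpha,
        "target_regions": list(spec.target_regions),
        "direction_mode": spec.direction_mode,
        "noise_sd": spec.noise_sd,
        "procedure_label": spec.procedure_label,
    }
    return SyntheticSubject(
        subject_id=subject.subject_id,
        class_label=subject.class_label,
        mesh=subject.mesh.with_vertices(post),
        truth=truth,
        stage="post",
        augmented=subject.augmented,
    )


# ---------------------------------------------------------------------------
# latent-space fixtures (encoder stand-ins for testing downstream stages)


@dataclass
class LatentFixtureSpec:
    """Gaussian class distributions in an R x d latent layout."""

    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    n_per_class: dict[str, int]
    layout: LatentLayout = field(default_factory=LatentLayout)
    seed: int = 0

    def validate(self) -> None:
        p = self.layout.total_width
        for cls in self.means:
            mu = np.asarray(self.means[cls], dtype=float)
            cov = np.asarray(self.covs[cls], dtype=float)
            if mu.shape != (p,) or cov.shape != (p, p):
                raise ValueError(f"dimension mismatch for class {cls!r}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance for {cls!r} not symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"covariance for {cls!r} not positive definite"
                ) from err


def sample_latent_fixture(spec: LatentFixtureSpec) -> pd.DataFrame:
    """Draw per-class Gaussian latents into a long table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    cols = spec.layout.column_names()
    for cls in sorted(spec.n_per_class):
        n = spec.n_per_class[cls]
        z = rng.multivariate_normal(
            np.asarray(spec.means[cls], dtype=float),
            np.asarray(spec.covs[cls], dtype=float),
            size=n,
            method="cholesky",
        )
        for i in range(n):
            rows.append(
                {"subject_id": f"{cls}_{i:03d}", "class_label": cls,
                 **dict(zip(cols, z[i]))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifest I/O


def write_manifest(subjects: list[SyntheticSubject], mesh_paths: list[str],
                   path: str) -> None:
    """Population manifest CSV: subject_id, class_label, mesh_path, stage,
    procedure_label, augmented."""
    rows = []
    for s, mp in zip(subjects, mesh_paths):
        proc = s.truth.get("surgery", {}).get("procedure_label", "")
        rows.append(
            {"subject_id": s.subject_id, "class_label": s.class_label,
             "mesh_path": mp, "stage": s.stage, "procedure_label": proc,
             "augmented": s.augmented}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
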