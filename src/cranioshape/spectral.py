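"""Spectral-interpolation augmentation of corresponded mesh populations.

Small syndromic cohorts are enlarged by blending same-class mesh pairs in a
truncated eigenbasis of the template's uniform (symmetric-normalized) graph
Laplacian: each coordinate channel is projected onto the first ``k``
eigenvectors, the coefficients of the two parents are mixed linearly with a
weight ``lam``, the out-of-basis residual is mixed with the same weight, and
the result is reconstructed.  Blending the residual (rather than dropping it)
makes ``lam = 0`` and ``lam = 1`` reproduce the parents exactly at any ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from cranioshape.mesh import CorrespondedMesh, Template, vertex_adjacency
from cranioshape.synthetic import SyntheticSubject


@dataclass
class SpectralBasis:
    """First ``k`` eigenpairs of the template's normalized graph Laplacian."""

    eigenvectors: np.ndarray  # N x k, orthonormal columns
    eigenvalues: np.ndarray   # k, ascending, first ~0
    template_id: str
    laplacian_kind: str = "uniform_graph"

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


def laplacian_basis(template: Template, k: int) -> SpectralBasis:
    """Compute the first ``k`` eigenpairs of ``L = I - D^-1/2 A D^-1/2``.

    Uses a dense eigendecomposition for small templates and shift-invert
    Lanczos otherwise; eigenvector signs are fixed deterministically.
    """
    n = template.mesh.n_vertices
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    adj = vertex_adjacency(template.mesh.faces, n).astype(float)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError("template mesh is disconnected")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = sp.identity(n) - sp.diags(d_isqrt) @ adj @ sp.diags(d_isqrt)
    if n <= 2000 or k > n - 2:
        vals, vecs = np.linalg.eigh(lap.toarray())
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        v0 = np.ones(n)
        vals, vecs = eigsh(lap.tocsc(), k=k, sigma=-0.01, which="LM", v0=v0)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return SpectralBasis(vecs, vals, template.template_id)


def spectral_interpolate(
    mesh_a: CorrespondedMesh,
    mesh_b: CorrespondedMesh,
    lam: float,
    basis: SpectralBasis,
) -> CorrespondedMesh:
    """Blend two corresponded meshes with weight ``lam`` in the eigenbasis."""
    if mesh_a.template_id != mesh_b.template_id:
        raise ValueError("meshes are on different templates")
    if mesh_a.template_id != basis.template_id:
        raise ValueError("basis built for a different template")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    phi = basis.eigenvectors
    va, vb = mesh_a.vertices, mesh_b.vertices
    ca, cb = phi.T @ va, phi.T @ vb          # k x 3 coefficients per channel
    ra, rb = va - phi @ ca, vb - phi @ cb    # out-of-basis residuals
    c = (1.0 - lam) * ca + lam * cb
    r = (1.0 - lam) * ra + lam * rb
    return mesh_a.with_vertices(phi @ c + r)


def band_energy(
    mesh: CorrespondedMesh, basis: SpectralBasis, band: slice
) -> float:
    """Squared spectral energy of the mesh coordinates in an eigenvalue band."""
    coeffs = basis.eigenvectors.T @ mesh.vertices
    return float((coeffs[band] ** 2).sum())


def augment_population(
    subjects: list[SyntheticSubject],
    n_target: int,
    template: Template,
    k: int = 128,
    lambda_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    skip_classes: tuple[str, ...] = ("healthy",),
    basis: SpectralBasis | None = None,
) -> list[SyntheticSubject]:
    """Grow every (non-skipped) class to ``n_target`` subjects.

    New subjects interpolate uniformly drawn same-class parent pairs at
    ``lam ~ Uniform(lambda_range)``; they inherit the class label and carry an
    ``augmented`` flag.  Deterministic given the seed.
    """
    if basis is None:
        basis = laplacian_basis(template, min(k, template.mesh.n_vertices))
    rng = np.random.default_rng(seed)
    out = list(subjects)
    lo, hi = lambda_range
    by_class: dict[str, list[SyntheticSubject]] = {}
    for s in subjects:
        by_class.setdefault(s.class_label, []).append(s)
    for cls in sorted(by_class):
        if cls in skip_classes:
            continue
        pool = by_class[cls]
        n_new = n_target - len(pool)
        if n_new <= 0:
            continue
        if len(pool) < 2:
            raise ValueError(
                f"class {cls!r} has {len(pool)} subject(s); need >= 2 to augment"
            )
        for j in range(n_new):
            ia, ib = rng.choice(len(pool), size=2, replace=False)
            lam = rng.uniform(lo, hi)
            mesh = spectral_interpolate(pool[ia].mesh, pool[ib].mesh, lam, basis)
            out.append(
                SyntheticSubject(
                    subject_id=f"{cls}_aug{j:03d}",
                    class_label=cls,
                    mesh=mesh,
                    truth={
                        "parents": [pool[ia].subject_id, pool[ib].subject_id],
                        "lambda": float(lam),
                    },
                    augmented=True,
                )
            )
    return out
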