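"""Figures: manifold arrows, regional-outcome boxplots, displacement heatmaps.

Every figure is regenerable from the exported tables alone; the functions
here take the already-computed objects and only draw.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse

from cranioshape.mesh import CorrespondedMesh, vertex_displacements
from cranioshape.stats import ManifoldProjection

#: Default colour saturation (mm) of displacement heatmaps: movements larger
#: than this render at the top of the colour scale.
DEFAULT_SATURATION_MM = 10.0


def _class_ellipse(mean: np.ndarray, cov: np.ndarray, n_sd: float = 2.0,
                   **kwargs) -> Ellipse:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    return Ellipse(
        xy=mean, width=2 * n_sd * np.sqrt(vals[-1]),
        height=2 * n_sd * np.sqrt(vals[0]), angle=angle, fill=False, **kwargs
    )


def plot_manifold(
    projection: ManifoldProjection,
    pair_coords: pd.DataFrame | None,
    path: str,
    contour_sds: tuple[float, ...] = (1.0, 2.0),
) -> None:
    """2D class contours plus one pre-to-post arrow per patient.

    ``pair_coords`` columns: patient_id, procedure_label, pre_x, pre_y,
    post_x, post_y.  Patients with pre == post render as a dot, not an arrow.
    """
    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for i, cls in enumerate(projection.classes):
        mu = projection.class_means_2d[cls]
        cov = projection.class_covs_2d[cls]
        ax.plot(*mu, "o", color=cmap(i), label=cls)
        for n_sd in contour_sds:
            ax.add_patch(_class_ellipse(mu, cov, n_sd, color=cmap(i), lw=1))
    if pair_coords is not None and len(pair_coords):
        procs = sorted(pair_coords["procedure_label"].unique())
        pc = plt.get_cmap("Dark2")
        for _, row in pair_coords.iterrows():
            color = pc(procs.index(row["procedure_label"]) % 8)
            dx = row["post_x"] - row["pre_x"]
            dy = row["post_y"] - row["pre_y"]
            if abs(dx) < 1e-12 and abs(dy) < 1e-12:
                ax.plot(row["pre_x"], row["pre_y"], ".", color=color)
            else:
                ax.annotate(
                    "", xy=(row["post_x"], row["post_y"]),
                    xytext=(row["pre_x"], row["pre_y"]),
                    arrowprops=dict(arrowstyle="->", color=color, lw=1.2),
                )
        for j, p in enumerate(procs):
            ax.plot([], [], "-", color=pc(j % 8), label=p)
    ax.set_xlabel("LD 1")
    ax.set_ylabel("LD 2")
    ax.legend(fontsize=8)
    ax.set_title("Latent manifold: pre-to-post surgical movements")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regional_boxplots(
    outcomes_long: pd.DataFrame, path: str, region_names: list[str] | None = None
) -> None:
    """Grouped boxes of m_r by region x procedure (groups ordered by region
    id then procedure name), with group sizes annotated."""
    df = outcomes_long
    groups = sorted(
        df.groupby(["region", "procedure_label"]).groups.keys()
    )
    data = [df[(df["region"] == r) & (df["procedure_label"] == p)]["m_r"].to_numpy()
            for r, p in groups]
    fig, ax = plt.subplots(figsize=(max(8, 0.5 * len(groups)), 5))
    ax.boxplot(data, tick_labels=[f"{r}:{p}" for r, p in groups])
    for i, d in enumerate(data, start=1):
        ax.annotate(f"n={len(d)}", (i, ax.get_ylim()[1]), fontsize=6,
                    ha="center", va="top")
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_ylabel("$m_r$")
    ax.set_xlabel("region : procedure")
    if region_names:
        ax.set_title(
            "Regional outcome metric ("
            + ", ".join(f"{i + 1}={n}" for i, n in enumerate(region_names[:6]))
            + ", ...)"
        )
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_displacement(
    pre: CorrespondedMesh,
    post: CorrespondedMesh,
    saturation_mm: float = DEFAULT_SATURATION_MM,
    path: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex displacement field with colour saturation.

    Returns ``(raw, clipped)``: raw distances (mm) are retained in full while
    the colour-mapped field is clipped at ``saturation_mm`` (movements beyond
    it all render at the top colour).  When ``path`` is given the field is
    rendered on the postoperative surface.
    """
    raw = vertex_displacements(pre, post)
    clipped = np.minimum(raw, saturation_mm)
    if path is not None:
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(111, projection="3d")
        v, f = post.vertices, post.faces
        face_vals = clipped[f].mean(axis=1)
        norm = plt.Normalize(0.0, saturation_mm)
        colors = plt.get_cmap("viridis")(norm(face_vals))
        coll = ax.plot_trisurf(
            v[:, 0], v[:, 1], v[:, 2], triangles=f, linewidth=0.0
        )
        coll.set_facecolors(colors)
        ax.view_init(elev=10, azim=-70)
        ax.set_axis_off()
        sm = plt.cm.ScalarMappable(norm=norm, cmap="viridis")
        fig.colorbar(sm, ax=ax, shrink=0.6,
                     label=f"displacement (mm, saturates at {saturation_mm:g})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return raw, clipped
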