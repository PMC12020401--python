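"""Regional surgical-outcome metric and patient / cohort outcome reports.

For every anatomic region ``r`` the surgery moves the regional latent subset
from ``z_pre^r`` to ``z_post^r``.  With ``mu_H^r`` and ``Sigma_H^r`` the mean
and covariance of the healthy distribution in that region, the outcome metric
is

    m_r = [ d_M(z_pre^r, z_post^r) / d_M(z_post^r, mu_H^r) ] * <s_r, v_H^r>,

where ``d_M`` is the Mahalanobis distance under ``Sigma_H^r``, ``s_r`` is the
versor (unit vector) of the surgical movement and ``v_H^r`` the versor from
the preoperative point toward the healthy mean.  Large positive values mean a
big movement, aligned with the ideal trajectory, ending close to the healthy
centre; negative values flag movement in the adverse direction.

Versors and the inner product live in the whitened regional space (coordinates
scaled by ``Sigma_H^r``^{-1/2}) so that directions and distances share one
geometry.  The ratio is floored at ``eps`` in the denominator, and zero
surgical movement yields m_r = 0 by convention; both degeneracies carry
explicit flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranioshape.latent import LatentVector
from cranioshape.stats import (
    ClassDistribution,
    ManifoldProjection,
    mahalanobis,
    whiten,
    whitening_matrix,
)

#: Norm below which a whitened movement counts as "no movement".
_NULL_TOL = 1e-12


@dataclass
class SurgicalPair:
    """A patient's pre/postoperative latent pair with its procedure label."""

    patient_id: str
    procedure_label: str
    z_pre: LatentVector
    z_post: LatentVector

    def __post_init__(self) -> None:
        if self.z_pre.layout != self.z_post.layout:
            raise ValueError("pre and post latents have different layouts")

    @property
    def layout(self):
        return self.z_pre.layout


@dataclass
class RegionalOutcome:
    """m_r and its components for one region of one patient."""

    region: int
    m_r: float
    magnitude: float      # d_M(z_pre^r, z_post^r)
    proximity: float      # d_M(z_post^r, mu_H^r)
    alignment: float      # <s_r, v_H^r> in [-1, 1]
    no_movement: bool = False
    denominator_floored: bool = False


@dataclass
class OutcomeReport:
    """Per-patient outcome: all regions plus the global picture."""

    patient_id: str
    procedure_label: str
    regional: list[RegionalOutcome]
    coords_pre_2d: np.ndarray | None = None
    coords_post_2d: np.ndarray | None = None
    global_dm_pre: float | None = None
    global_dm_post: float | None = None
    displacement_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# versors


def _unit(v: np.ndarray) -> tuple[np.ndarray, bool]:
    n = float(np.linalg.norm(v))
    if n < _NULL_TOL:
        return np.zeros_like(v), True
    return v / n, False


def surgical_versor(
    z_pre_r: np.ndarray, z_post_r: np.ndarray, healthy_dist_r: ClassDistribution
) -> tuple[np.ndarray, bool]:
    """Unit direction of the surgical movement in the whitened regional
    space; returns ``(versor, is_null)`` — a null versor is flagged, never an
    error."""
    w_pre = whiten(z_pre_r, healthy_dist_r)
    w_post = whiten(z_post_r, healthy_dist_r)
    return _unit(w_post - w_pre)


def healthy_versor(
    z_pre_r: np.ndarray, healthy_dist_r: ClassDistribution
) -> tuple[np.ndarray, bool]:
    """Unit direction from the preoperative point toward the healthy mean in
    the whitened regional space (the ideal trajectory)."""
    w_pre = whiten(z_pre_r, healthy_dist_r)
    return _unit(-w_pre)


# ---------------------------------------------------------------------------
# the metric


def regional_metric(
    pair: SurgicalPair,
    r: int,
    healthy_dist_r: ClassDistribution,
    eps: float = 1e-6,
    form: str = "ratio",
) -> RegionalOutcome:
    """Evaluate m_r for one region.

    ``form="ratio"`` (default) divides the movement magnitude by the residual
    distance to the healthy mean; ``form="product"`` multiplies them instead
    (the alternative typographic reading, kept for comparison).
    """
    if form not in ("ratio", "product"):
        raise ValueError(f"unknown metric form {form!r}")
    zp = pair.z_pre.subset(r)
    zq = pair.z_post.subset(r)
    if zp.size != healthy_dist_r.dim:
        raise ValueError("regional latent width does not match distribution")
    magnitude = mahalanobis(zp, zq, healthy_dist_r)
    proximity = mahalanobis(zq, healthy_dist_r.mean, healthy_dist_r)
    s_r, null_move = surgical_versor(zp, zq, healthy_dist_r)
    v_h, _null_pre = healthy_versor(zp, healthy_dist_r)
    alignment = float(np.clip(s_r @ v_h, -1.0, 1.0))
    if null_move:
        return RegionalOutcome(
            region=r, m_r=0.0, magnitude=magnitude, proximity=proximity,
            alignment=0.0, no_movement=True,
        )
    floored = proximity < eps
    if form == "ratio":
        m = magnitude / max(proximity, eps) * alignment
    else:
        m = magnitude * proximity * alignment
    return RegionalOutcome(
        region=r, m_r=float(m), magnitude=magnitude, proximity=proximity,
        alignment=alignment, denominator_floored=bool(floored),
    )


def assess_patient(
    pair: SurgicalPair,
    dists: dict[str, ClassDistribution],
    projection: ManifoldProjection | None = None,
    healthy_label: str = "healthy",
    eps: float = 1e-6,
    form: str = "ratio",
    displacements: np.ndarray | None = None,
) -> OutcomeReport:
    """Full outcome report for one patient.

    Computes m_r for every region, the global Mahalanobis distance to the
    healthy mean before and after surgery, and (when a frozen projection is
    supplied) the 2D manifold coordinates of the pre/post latents.  An
    optional per-vertex displacement field is summarized, not stored.
    """
    healthy = dists[healthy_label]
    if healthy.layout != pair.layout:
        raise ValueError("distribution layout does not match the pair")
    regional = [
        regional_metric(pair, r, healthy.region(r), eps=eps, form=form)
        for r in range(1, pair.layout.n_regions + 1)
    ]
    report = OutcomeReport(
        patient_id=pair.patient_id,
        procedure_label=pair.procedure_label,
        regional=regional,
        global_dm_pre=mahalanobis(pair.z_pre.values, healthy.mean, healthy),
        global_dm_post=mahalanobis(pair.z_post.values, healthy.mean, healthy),
    )
    if projection is not None:
        coords = projection.project(
            np.vstack([pair.z_pre.values, pair.z_post.values])
        )
        report.coords_pre_2d = coords[0]
        report.coords_post_2d = coords[1]
    if displacements is not None:
        d = np.asarray(displacements, dtype=float)
        report.displacement_summary = {
            "mean_mm": float(d.mean()),
            "max_mm": float(d.max()),
            "p95_mm": float(np.percentile(d, 95)),
        }
    return report


# ---------------------------------------------------------------------------
# cohort summaries


def report_to_rows(report: OutcomeReport) -> list[dict]:
    return [
        {
            "patient_id": report.patient_id,
            "procedure_label": report.procedure_label,
            "region": ro.region,
            "m_r": ro.m_r,
            "magnitude": ro.magnitude,
            "proximity": ro.proximity,
            "alignment": ro.alignment,
            "no_movement": ro.no_movement,
            "denominator_floored": ro.denominator_floored,
        }
        for ro in report.regional
    ]


def outcomes_long_table(reports: list[OutcomeReport]) -> pd.DataFrame:
    """Long-format table (patient, procedure, region, m_r, components, flags)."""
    rows: list[dict] = []
    for rep in reports:
        rows.extend(report_to_rows(rep))
    return pd.DataFrame(rows)


def cohort_summary(reports: list[OutcomeReport]) -> pd.DataFrame:
    """Per-procedure, per-region summary (median, quartiles, n, flag counts)
    suitable for boxplotting."""
    if not reports:
        raise ValueError("no reports to summarize")
    df = outcomes_long_table(reports)
    g = df.groupby(["procedure_label", "region"])
    out = g["m_r"].agg(
        median="median",
        q1=lambda x: x.quantile(0.25),
        q3=lambda x: x.quantile(0.75),
        n="count",
    )
    out["n_no_movement"] = g["no_movement"].sum()
    out["n_floored"] = g["denominator_floored"].sum()
    return out.reset_index()
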