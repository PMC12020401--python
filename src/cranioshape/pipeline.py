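"""End-to-end orchestration of the synthetic surgical-outcome study.

Stages (in order): synth -> augment -> train -> embed -> fit distributions ->
classify -> project -> assess -> report.  One global seed determines every
stochastic stage; two runs with the same config produce identical CSV
artifacts.  Each stage writes its outputs into the run directory and can be
resumed from cached predecessors.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranioshape import autoencoder as ae
from cranioshape import synthetic as syn
from cranioshape.mesh import write_mesh, write_partition
from cranioshape.outcome import (
    OutcomeReport,
    SurgicalPair,
    assess_patient,
    cohort_summary,
    outcomes_long_table,
    report_to_rows,
)
from cranioshape.plotting import (
    DEFAULT_SATURATION_MM,
    heatmap_displacement,
    plot_manifold,
    plot_regional_boxplots,
)
from cranioshape.spectral import augment_population
from cranioshape.stats import (
    confusion_and_precision,
    fit_class_distributions,
    lda_fit_project,
    qda_predict_batch,
)


@dataclass
class ProcedureSpec:
    """Synthetic analogue of one osteotomy procedure."""

    label: str
    target_regions: tuple[int, ...]
    completeness: float
    noise_sd: float = 0.3


#: Default synthetic procedures.  Region ids refer to the default 15-region
#: template; the "lefort3" analogue deliberately leaves the frontal (1) and
#: supraorbital (2) regions untouched, mirroring a subcranial approach.
DEFAULT_PROCEDURES = (
    ProcedureSpec("monobloc", (1, 2, 5, 6), 0.8),
    ProcedureSpec("lefort3", (5, 6, 9, 10), 0.7),
    ProcedureSpec("bipartition", (3, 4, 6), 0.5),
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the study conditions."""

    n_subdivisions: int = 3
    n_regions: int = 15
    population: syn.PopulationSpec = field(default_factory=syn.PopulationSpec)
    n_heldout_per_class: int = 10
    augment_to: int = 60
    basis_k: int = 128
    lambda_range: tuple[float, float] = (0.2, 0.8)
    model: ae.ModelConfig | None = None
    procedures: tuple[ProcedureSpec, ...] = DEFAULT_PROCEDURES
    n_patients_per_procedure: int = 5
    shrinkage: float | str = "auto"
    fit_healthy_on_augmented: bool = False
    metric_eps: float = 1e-6
    metric_form: str = "ratio"
    heatmap_saturation_mm: float = DEFAULT_SATURATION_MM
    write_meshes: bool = False
    template_path: str | None = None  # optional pre-existing template mesh
    seed: int = 0

    def validate(self) -> None:
        self.population.validate()
        if self.template_path is not None and not os.path.exists(self.template_path):
            raise FileNotFoundError(
                f"configured template path does not exist: {self.template_path}"
            )
        if self.metric_form not in ("ratio", "product"):
            raise ValueError(f"unknown metric form {self.metric_form!r}")
        if self.augment_to < 2:
            raise ValueError("augment_to must be >= 2")

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        with open(path, "rb") as f:
            raw = tomllib.load(f)
        cfg = cls()
        pop = raw.pop("population", {})
        for k, v in pop.items():
            if k == "region_effects":
                v = {c: {int(r): float(e) for r, e in d.items()}
                     for c, d in v.items()}
            setattr(cfg.population, k, v)
        model = raw.pop("model", {})
        if model:
            cfg.model = ae.ModelConfig(**model)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


class RunLog:
    """Timestamped stage log; every resolved default is recorded."""

    def __init__(self, path: str):
        self.path = path
        self.t0 = time.time()
        self._lines: list[str] = []

    def log(self, msg: str) -> None:
        line = f"[{time.time() - self.t0:8.1f}s] {msg}"
        self._lines.append(line)
        with open(self.path, "a") as f:
            f.write(line + "\n")

    def log_config(self, config: PipelineConfig) -> None:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        self.log("resolved config: "
                 + json.dumps(dataclasses.asdict(config), default=_default))


def _seed(base: int, k: int) -> int:
    return int((base * 1000003 + k) % (2**31 - 1))


def run_pipeline(
    config: PipelineConfig, out_dir: str, resume: bool = False
) -> dict:
    """Execute the full study; returns the in-memory results dictionary.

    Artifacts written under ``out_dir``: latent tables, confusion matrix,
    manifold coordinates, outcome tables and per-patient JSON reports,
    figures, and the run log.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    log = RunLog(os.path.join(out_dir, "run_log.txt"))
    log.log_config(config)

    # --- synth ------------------------------------------------------------
    log.log("stage synth: building template and cohort")
    template = syn.make_template(
        config.n_subdivisions, seed=_seed(config.seed, 1),
        n_regions=config.n_regions,
    )
    pop_spec = dataclasses.replace(
        config.population, seed=_seed(config.seed, 2)
    )
    train_subjects = syn.sample_population(pop_spec, template)
    held_spec = dataclasses.replace(
        pop_spec,
        n_per_class={c: config.n_heldout_per_class
                     for c in pop_spec.n_per_class},
    )
    heldout = syn.sample_population(
        held_spec, template, draw_seed=_seed(config.seed, 3), id_prefix="ho"
    )
    healthy_mean = syn.class_mean_mesh(train_subjects, "healthy")
    if config.write_meshes:
        mesh_dir = os.path.join(out_dir, "meshes")
        os.makedirs(mesh_dir, exist_ok=True)
        write_partition(template.partition,
                        os.path.join(out_dir, "template_partition.csv"))
        write_mesh(template.mesh, os.path.join(mesh_dir, "template.ply"))
        paths = []
        for s in train_subjects:
            p = os.path.join(mesh_dir, f"{s.subject_id}.ply")
            write_mesh(s.mesh, p)
            paths.append(p)
        syn.write_manifest(train_subjects, paths,
                           os.path.join(out_dir, "manifest.csv"))

    # --- surgery (synthetic patients) --------------------------------------
    log.log("stage synth: simulating surgical pairs")
    syndromic = [s for s in heldout if s.class_label != "healthy"]
    pairs_meshes = []
    i = 0
    for proc in config.procedures:
        for _ in range(config.n_patients_per_procedure):
            subj = syndromic[i % len(syndromic)]
            i += 1
            sspec = syn.SurgerySpec(
                target_regions=proc.target_regions,
                completeness=proc.completeness,
                noise_sd=proc.noise_sd,
                procedure_label=proc.label,
                seed=_seed(config.seed, 100 + i),
            )
            post = syn.apply_surgery(subj, sspec, healthy_mean, template)
            pairs_meshes.append((subj, post, proc.label))

    # --- augment ------------------------------------------------------------
    log.log(f"stage augment: growing classes to {config.augment_to}")
    augmented = augment_population(
        train_subjects, config.augment_to, template,
        k=config.basis_k, lambda_range=config.lambda_range,
        seed=_seed(config.seed, 4),
    )
    log.log(f"augmented cohort size: {len(augmented)}")

    # --- train ----------------------------------------------------------------
    model_cfg = config.model or ae.ModelConfig(
        n_regions=config.n_regions, seed=_seed(config.seed, 5)
    )
    ckpt = os.path.join(out_dir, "model.npz")
    if resume and os.path.exists(ckpt):
        log.log("stage train: resuming from cached checkpoint")
        model = ae.load_model(ckpt, template)
    else:
        log.log(f"stage train: {model_cfg.epochs} epochs on "
                f"{len(augmented)} meshes")
        model = ae.train([s.mesh for s in augmented], template, model_cfg)
        ae.save_model(model, ckpt)
        log.log("final training loss: "
                f"{model.training_log['total'].iloc[-1]:.6f}")
    model.training_log.to_csv(os.path.join(out_dir, "training_log.csv"),
                              index=False)

    # --- embed ---------------------------------------------------------------
    log.log("stage embed: encoding cohorts")
    lat_train = ae.encode_population(model, augmented)
    lat_held = ae.encode_population(model, heldout)
    lat_train.to_csv(os.path.join(out_dir, "latents_train.csv"), index=False)
    lat_held.to_csv(os.path.join(out_dir, "latents_heldout.csv"), index=False)

    # --- fit distributions ---------------------------------------------------
    fit_table = lat_train
    if not config.fit_healthy_on_augmented:
        fit_table = lat_train[
            (lat_train["class_label"] != "healthy") | (~lat_train["augmented"])
        ]
    dists = fit_class_distributions(
        fit_table, fit_table["class_label"], layout=model.layout,
        shrinkage=config.shrinkage,
    )

    # --- classify ------------------------------------------------------------
    log.log("stage classify: QDA on held-out subjects")
    pred = qda_predict_batch(dists, lat_held)
    cm = confusion_and_precision(lat_held["class_label"].to_numpy(), pred)
    cm.counts.to_csv(os.path.join(out_dir, "confusion_matrix.csv"))
    with open(os.path.join(out_dir, "precision.json"), "w") as f:
        json.dump(cm.precision, f, indent=2)
    log.log(f"per-class precision: {cm.precision}")

    # --- project -------------------------------------------------------------
    projection, _ = lda_fit_project(lat_train, lat_train["class_label"])

    # --- assess --------------------------------------------------------------
    log.log("stage assess: regional outcome metric per patient")
    reports: list[OutcomeReport] = []
    pair_rows = []
    for pre_s, post_s, proc in pairs_meshes:
        z_pre = ae.encode(model, pre_s.mesh)
        z_post = ae.encode(model, post_s.mesh)
        pair = SurgicalPair(pre_s.subject_id, proc, z_pre, z_post)
        disp, _ = heatmap_displacement(
            pre_s.mesh, post_s.mesh,
            saturation_mm=config.heatmap_saturation_mm,
        )
        rep = assess_patient(
            pair, dists, projection, eps=config.metric_eps,
            form=config.metric_form, displacements=disp,
        )
        reports.append(rep)
        pair_rows.append({
            "patient_id": pair.patient_id, "procedure_label": proc,
            "pre_x": rep.coords_pre_2d[0], "pre_y": rep.coords_pre_2d[1],
            "post_x": rep.coords_post_2d[0], "post_y": rep.coords_post_2d[1],
        })
    outcomes = outcomes_long_table(reports)
    outcomes.to_csv(os.path.join(out_dir, "outcomes_long.csv"), index=False)
    summary = cohort_summary(reports)
    summary.to_csv(os.path.join(out_dir, "outcome_summary.csv"), index=False)
    pair_coords = pd.DataFrame(pair_rows)
    pair_coords.to_csv(os.path.join(out_dir, "pair_coords_2d.csv"), index=False)
    report_dir = os.path.join(out_dir, "patient_reports")
    os.makedirs(report_dir, exist_ok=True)
    for rep in reports:
        with open(os.path.join(report_dir, f"{rep.patient_id}.json"), "w") as f:
            json.dump({
                "patient_id": rep.patient_id,
                "procedure_label": rep.procedure_label,
                "global_dm_pre": rep.global_dm_pre,
                "global_dm_post": rep.global_dm_post,
                "displacement_summary": rep.displacement_summary,
                "regional": report_to_rows(rep),
            }, f, indent=2)

    # --- report (figures) ----------------------------------------------------
    log.log("stage report: figures")
    plot_manifold(projection, pair_coords,
                  os.path.join(out_dir, "manifold_arrows.png"))
    plot_regional_boxplots(outcomes,
                           os.path.join(out_dir, "regional_boxplots.png"),
                           template.partition.region_names)
    pre0, post0, _ = pairs_meshes[0]
    heatmap_displacement(
        pre0.mesh, post0.mesh, config.heatmap_saturation_mm,
        path=os.path.join(out_dir, "displacement_heatmap.png"),
    )
    log.log("pipeline complete")
    return {
        "template": template,
        "model": model,
        "distributions": dists,
        "projection": projection,
        "confusion": cm,
        "reports": reports,
        "outcomes": outcomes,
        "summary": summary,
    }
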