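"""Toy region-disentangled variational autoencoder for corresponded meshes.

The model maps a mesh in template correspondence to an ``R x d`` latent vector
whose d-wide subsets each control one anatomic region.  Disentanglement is
obtained architecturally: region ``r`` has its own encoder (seeing only the
region's centered vertex block) and its own decoder (emitting only that
block), so a latent subset cannot influence other regions except through the
light boundary smoothing applied at decode time.  A swap-consistency penalty
on mesh-space hybrids (region content of one subject blended into another via
:func:`region_swap`) keeps the contract honest at region boundaries, where
the blocks do interact.

Everything is NumPy with manual backpropagation and Adam; networks default to
linear maps (probabilistic-PCA-like per region), with optional tanh hidden
layers.  Training and inference are deterministic given the config seed;
inference uses the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from cranioshape.latent import LatentLayout, LatentVector
from cranioshape.mesh import (
    CorrespondedMesh,
    RegionPartition,
    Template,
    blend_weights,
    region_vertices,
    vertex_adjacency,
)


@dataclass
class ModelConfig:
    """Hyperparameters of the toy disentangled autoencoder.

    ``n_regions * latent_per_region`` is the total latent width (75 at the
    defaults).  ``beta`` weighs the divergence of the diagonal-Gaussian
    posterior from the unit-Gaussian prior; ``mean_anchor`` adds extra weight
    on the posterior-mean part of that divergence (keeping the latent scale
    near the prior's, which stabilizes the swap penalty); ``gamma`` weighs
    the swap-consistency penalty.
    """

    n_regions: int = 15
    latent_per_region: int = 5
    hidden_sizes: tuple[int, ...] = ()
    recon_weight: float = 1.0
    beta: float = 0.01
    mean_anchor: float = 0.1
    gamma: float = 1.0
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 0.01
    n_swap: int = 16
    seed: int = 0

    @property
    def latent_width(self) -> int:
        return self.n_regions * self.latent_per_region

    def validate(self) -> None:
        if min(self.recon_weight, self.beta, self.gamma,
               self.mean_anchor) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training schedule")


class _MLP:
    """Minimal tanh MLP (linear when no hidden layers) with manual backprop."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_bias: np.ndarray | None = None):
        self.params: list[list[np.ndarray]] = []
        for i in range(len(sizes) - 1):
            w = rng.normal(size=(sizes[i], sizes[i + 1])) / np.sqrt(sizes[i])
            if i < len(sizes) - 2:
                w *= 1.0
            else:
                w *= 0.1
            b = np.zeros(sizes[i + 1])
            self.params.append([w, b])
        if out_bias is not None:
            self.params[-1][1][:] = out_bias

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        a = x
        for i, (w, b) in enumerate(self.params):
            a = a @ w + b
            if i < len(self.params) - 1:
                a = np.tanh(a)
            acts.append(a)
        return a, acts

    def backward(
        self, grad_out: np.ndarray, acts: list[np.ndarray]
    ) -> tuple[list[list[np.ndarray]], np.ndarray]:
        grads: list[list[np.ndarray]] = [None] * len(self.params)  # type: ignore
        g = grad_out
        for i in reversed(range(len(self.params))):
            w, _ = self.params[i]
            a_in = acts[i]
            grads[i] = [a_in.T @ g, g.sum(axis=0)]
            g = g @ w.T
            if i > 0:  # derivative of the tanh that produced acts[i]
                g = g * (1.0 - acts[i] ** 2)
        return grads, g

    def zero_like(self) -> list[list[np.ndarray]]:
        return [[np.zeros_like(w), np.zeros_like(b)] for w, b in self.params]


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr, self.b1, self.b2, self.eps, self.t = lr, 0.9, 0.999, 1e-8, 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        b1t, b2t = 1 - self.b1**self.t, 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """Fitted encoder/decoder with normalization stats and training log."""

    config: ModelConfig
    template: Template
    encoders: list[_MLP]
    decoders: list[_MLP]
    vertex_mean: np.ndarray   # (N, 3) training mean per vertex
    scale: float              # global std of centered coordinates
    layout: LatentLayout
    training_log: pd.DataFrame
    _region_idx: list[np.ndarray] = field(default_factory=list)
    _smoother: sp.csr_matrix | None = None


# ---------------------------------------------------------------------------
# region swap (mesh-space hybrids)


def region_swap(
    mesh_a: CorrespondedMesh,
    mesh_b: CorrespondedMesh,
    r: int,
    partition: RegionPartition,
) -> CorrespondedMesh:
    """Hybrid mesh: region ``r`` taken from B, the rest from A, blended over a
    two-ring falloff at the region boundary."""
    if mesh_a.template_id != mesh_b.template_id:
        raise ValueError("meshes are on different templates")
    idx = region_vertices(partition, r)
    adj = vertex_adjacency(mesh_a.faces, mesh_a.n_vertices)
    w = blend_weights(adj, idx, mesh_a.n_vertices, rings=2)
    v = mesh_a.vertices + w[:, None] * (mesh_b.vertices - mesh_a.vertices)
    v[w >= 1.0] = mesh_b.vertices[w >= 1.0]  # swapped region is bit-exact
    return mesh_a.with_vertices(v)


def _swap_weights(template: Template) -> list[np.ndarray]:
    adj = vertex_adjacency(template.mesh.faces, template.mesh.n_vertices)
    return [
        blend_weights(adj, region_vertices(template.partition, r),
                      template.mesh.n_vertices, rings=2)
        for r in range(1, template.n_regions + 1)
    ]


def _boundary_smoother(template: Template) -> sp.csr_matrix:
    """Linear operator averaging region-boundary vertices with their one-ring
    (0.5 self + 0.5 neighbour mean); identity elsewhere."""
    n = template.mesh.n_vertices
    adj = vertex_adjacency(template.mesh.faces, n)
    labels = template.partition.labels
    indptr, indices = adj.indptr, adj.indices
    rows, cols, vals = [], [], []
    for v in range(n):
        nbrs = indices[indptr[v]:indptr[v + 1]]
        if np.any(labels[nbrs] != labels[v]):
            rows.append(v); cols.append(v); vals.append(0.5)
            wn = 0.5 / len(nbrs)
            for u in nbrs:
                rows.append(v); cols.append(int(u)); vals.append(wn)
        else:
            rows.append(v); cols.append(v); vals.append(1.0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# training


def _blocks(x: np.ndarray, region_idx: list[np.ndarray]) -> list[np.ndarray]:
    """Split normalized (n, N, 3) coordinates into flat per-region blocks."""
    return [x[:, idx, :].reshape(x.shape[0], -1) for idx in region_idx]


def train(
    meshes: list[CorrespondedMesh],
    template: Template,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit the disentangled autoencoder on a corresponded population.

    Minimizes reconstruction MSE + ``beta`` * KL(posterior || unit Gaussian)
    + ``gamma`` * swap-consistency (latents of mesh-space hybrids must match
    the swapped subset of one parent and the remaining subsets of the other).
    Deterministic given ``config.seed``; raises if the loss turns non-finite.
    """
    config = config or ModelConfig(n_regions=template.n_regions)
    config.validate()
    if config.n_regions != template.n_regions:
        raise ValueError(
            f"config.n_regions={config.n_regions} != template regions "
            f"{template.n_regions}"
        )
    if len(meshes) < 2:
        raise ValueError("need at least 2 training meshes")
    for m in meshes:
        if m.template_id != template.template_id or m.n_vertices != template.mesh.n_vertices:
            raise ValueError("training mesh not on the model template")

    rng = np.random.default_rng(config.seed)
    X = np.stack([m.vertices for m in meshes])            # (n, N, 3)
    vertex_mean = X.mean(axis=0)
    Xc = X - vertex_mean
    scale = float(Xc.std())  # std of centered residuals, not raw coordinates
    if scale <= 0:
        scale = 1.0
    Xn = Xc / scale
    region_idx = [
        region_vertices(template.partition, r)
        for r in range(1, template.n_regions + 1)
    ]
    blocks = _blocks(Xn, region_idx)
    d = config.latent_per_region
    encoders, decoders = [], []
    for idx in region_idx:
        p = 3 * len(idx)
        enc_sizes = [p, *config.hidden_sizes, 2 * d]
        out_bias = np.concatenate([np.zeros(d), -6.0 * np.ones(d)])
        encoders.append(_MLP(enc_sizes, rng, out_bias=out_bias))
        dec_sizes = [d, *reversed(config.hidden_sizes), p]
        decoders.append(_MLP(dec_sizes, rng))

    all_params: list[np.ndarray] = []
    for net in encoders + decoders:
        for w, b in net.params:
            all_params.extend([w, b])
    adam = _Adam([p.shape for p in all_params], config.learning_rate)
    swap_w = _swap_weights(template) if config.gamma > 0 else None
    smoother = _boundary_smoother(template)
    smoother_t = smoother.T.tocsr()
    n_vertices = template.mesh.n_vertices

    def _apply_op(op: sp.csr_matrix, y: np.ndarray) -> np.ndarray:
        """Apply a vertex-space linear operator to a (b, N, 3) batch."""
        b_ = y.shape[0]
        flat = y.transpose(1, 0, 2).reshape(n_vertices, b_ * 3)
        return (op @ flat).reshape(n_vertices, b_, 3).transpose(1, 0, 2)

    n = len(meshes)
    n_coord = Xn.size // n  # 3N
    log_rows = []
    for epoch in range(config.epochs):
        # cosine decay bounds optimizer drift along the scale degeneracy of
        # paired linear encoder/decoder maps
        lr_scale = 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(n)
        ep_recon = ep_kl = ep_swap = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            b = len(sel)
            grad_acc = {id(p): np.zeros_like(p) for p in all_params}

            def _accumulate(net: _MLP, grads) -> None:
                for (w, bias), (gw, gb) in zip(net.params, grads):
                    grad_acc[id(w)] += gw
                    grad_acc[id(bias)] += gb

            # forward every region, assemble the full mesh prediction, apply
            # the boundary smoother (part of the decode path, so the model
            # learns to compensate its bias), then backpropagate through it
            batch_mu, fwd = [], []
            yhat = np.zeros((b, n_vertices, 3))
            for r in range(config.n_regions):
                xr = blocks[r][sel]
                out, enc_acts = encoders[r].forward(xr)
                mu, lv = out[:, :d], np.clip(out[:, d:], -8.0, 4.0)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(0.5 * lv)
                z = mu + eps * std
                xhat, dec_acts = decoders[r].forward(z)
                idx = region_idx[r]
                yhat[:, idx, :] = xhat.reshape(b, len(idx), 3)
                fwd.append((mu, lv, eps, std, enc_acts, dec_acts))
                batch_mu.append(mu)
            diff = _apply_op(smoother, yhat) - Xn[sel]
            ep_recon += float((diff**2).sum()) / (b * n_coord)
            g_y = _apply_op(
                smoother_t, (2.0 * config.recon_weight / (b * n_coord)) * diff
            )
            n_lat = b * config.latent_width
            for r in range(config.n_regions):
                mu, lv, eps, std, enc_acts, dec_acts = fwd[r]
                g_xhat = g_y[:, region_idx[r], :].reshape(b, -1)
                dec_grads, g_z = decoders[r].backward(g_xhat, dec_acts)
                _accumulate(decoders[r], dec_grads)
                # KL divergence to the unit Gaussian prior (per latent
                # dimension).  The posterior means get an additional anchor
                # weight: it pins the latent scale near the prior's so the
                # swap-consistency penalty cannot be diluted by inflating
                # latents, while beta alone sets the (much cheaper) posterior
                # noise floor.
                kl = 0.5 * (mu**2 + np.exp(lv) - 1.0 - lv)
                ep_kl += float(kl.sum()) / n_lat
                g_mu = g_z + (config.beta + config.mean_anchor) * mu / n_lat
                g_lv = (g_z * eps * 0.5 * std
                        + config.beta * 0.5 * (np.exp(lv) - 1.0) / n_lat)
                enc_grads, _ = encoders[r].backward(
                    np.concatenate([g_mu, g_lv], axis=1), enc_acts
                )
                _accumulate(encoders[r], enc_grads)

            if config.gamma > 0 and b >= 2:
                n_swap = min(config.n_swap, b * (b - 1))
                ii = rng.integers(0, b, size=n_swap)
                jj = (ii + 1 + rng.integers(0, b - 1, size=n_swap)) % b
                rr = rng.integers(0, config.n_regions, size=n_swap)
                xa, xb_ = Xn[sel[ii]], Xn[sel[jj]]
                hyb = xa.copy()
                for t in range(n_swap):
                    w_r = swap_w[rr[t]][:, None]
                    hyb[t] = xa[t] + w_r * (xb_[t] - xa[t])
                hyb_blocks = _blocks(hyb, region_idx)
                d_total = n_swap * config.latent_width
                for s in range(config.n_regions):
                    out_h, acts_h = encoders[s].forward(hyb_blocks[s])
                    mu_h = out_h[:, :d]
                    tgt = batch_mu[s][ii].copy()
                    swapped = rr == s
                    tgt[swapped] = batch_mu[s][jj[swapped]]
                    diff_h = mu_h - tgt
                    ep_swap += float((diff_h**2).sum()) / d_total
                    g_out = np.zeros_like(out_h)
                    g_out[:, :d] = 2.0 * config.gamma / d_total * diff_h
                    grads_h, _ = encoders[s].backward(g_out, acts_h)
                    _accumulate(encoders[s], grads_h)

            adam.step(all_params, [grad_acc[id(p)] for p in all_params],
                      lr_scale=lr_scale)
            n_batches += 1

        row = {
            "epoch": epoch,
            "recon": ep_recon / n_batches,
            "kl": ep_kl / n_batches,
            "swap": ep_swap / n_batches,
        }
        row["total"] = (config.recon_weight * row["recon"]
                        + config.beta * row["kl"] + config.gamma * row["swap"])
        if not np.isfinite(row["total"]):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        log_rows.append(row)

    return TrainedModel(
        config=config,
        template=template,
        encoders=encoders,
        decoders=decoders,
        vertex_mean=vertex_mean,
        scale=scale,
        layout=LatentLayout(config.n_regions, d),
        training_log=pd.DataFrame(log_rows),
        _region_idx=region_idx,
        _smoother=smoother,
    )


# ---------------------------------------------------------------------------
# inference


def encode(model: TrainedModel, mesh: CorrespondedMesh) -> LatentVector:
    """Posterior-mean latent of a mesh (deterministic)."""
    t = model.template
    if mesh.template_id != t.template_id or mesh.n_vertices != t.mesh.n_vertices:
        raise ValueError("mesh is not on the model's template")
    xn = (mesh.vertices - model.vertex_mean) / model.scale
    d = model.config.latent_per_region
    parts = []
    for r, idx in enumerate(model._region_idx):
        out, _ = model.encoders[r].forward(xn[idx].reshape(1, -1))
        parts.append(out[0, :d])
    return LatentVector(np.concatenate(parts), model.layout)


def encode_population(
    model: TrainedModel, subjects, extra_cols: bool = True
) -> pd.DataFrame:
    """Latent table (subject_id, class_label, stage, z_001..) for a cohort of
    :class:`~cranioshape.synthetic.SyntheticSubject` objects."""
    rows = []
    cols = model.layout.column_names()
    for s in subjects:
        z = encode(model, s.mesh)
        row = {"subject_id": s.subject_id, "class_label": s.class_label}
        if extra_cols:
            row["stage"] = s.stage
            row["augmented"] = s.augmented
        row.update(dict(zip(cols, z.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def decode(model: TrainedModel, latent: LatentVector) -> CorrespondedMesh:
    """Reconstruct a mesh from a latent vector, with boundary smoothing."""
    if latent.layout != model.layout:
        raise ValueError("latent layout does not match the model")
    n = model.template.mesh.n_vertices
    y = np.zeros((n, 3))
    for r, idx in enumerate(model._region_idx):
        block, _ = model.decoders[r].forward(latent.subset(r + 1)[None, :])
        y[idx] = block[0].reshape(len(idx), 3)
    y = model._smoother @ y
    v = y * model.scale + model.vertex_mean
    return CorrespondedMesh(v, model.template.mesh.faces, model.template.template_id)


def reconstruction_error(model: TrainedModel, meshes) -> float:
    """Mean per-vertex Euclidean reconstruction error (mm)."""
    errs = []
    for m in meshes:
        rec = decode(model, encode(model, m))
        errs.append(np.linalg.norm(rec.vertices - m.vertices, axis=1).mean())
    return float(np.mean(errs))


def save_model(model: TrainedModel, path: str) -> None:
    """Persist a checkpoint (parameters, config, normalization, template id)."""
    import json

    arrays: dict[str, np.ndarray] = {
        "vertex_mean": model.vertex_mean,
        "scale": np.array([model.scale]),
    }
    for kind, nets in (("enc", model.encoders), ("dec", model.decoders)):
        for r, net in enumerate(nets):
            for li, (w, b) in enumerate(net.params):
                arrays[f"{kind}_{r}_{li}_w"] = w
                arrays[f"{kind}_{r}_{li}_b"] = b
    meta = {
        "config": dataclasses_asdict(model.config),
        "template_id": model.template.template_id,
        "n_layers": len(model.encoders[0].params),
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    model.training_log.to_csv(str(path) + ".log.csv", index=False)


def dataclasses_asdict(cfg: ModelConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(cfg)
    d["hidden_sizes"] = list(d["hidden_sizes"])
    return d


def load_model(path: str, template: Template) -> TrainedModel:
    """Restore a checkpoint; the caller supplies the (matching) template."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["template_id"] != template.template_id:
            raise ValueError("checkpoint was trained on a different template")
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        config = ModelConfig(**cfg_d)
        rng = np.random.default_rng(0)
        encoders, decoders = [], []
        region_idx = [
            region_vertices(template.partition, r)
            for r in range(1, template.n_regions + 1)
        ]
        d = config.latent_per_region
        for r, idx in enumerate(region_idx):
            p = 3 * len(idx)
            enc = _MLP([p, *config.hidden_sizes, 2 * d], rng)
            dec = _MLP([d, *reversed(config.hidden_sizes), p], rng)
            for li in range(len(enc.params)):
                enc.params[li][0] = data[f"enc_{r}_{li}_w"]
                enc.params[li][1] = data[f"enc_{r}_{li}_b"]
            for li in range(len(dec.params)):
                dec.params[li][0] = data[f"dec_{r}_{li}_w"]
                dec.params[li][1] = data[f"dec_{r}_{li}_b"]
            encoders.append(enc)
            decoders.append(dec)
        vertex_mean = data["vertex_mean"]
        scale = float(data["scale"][0])
    try:
        log = pd.read_csv(str(path) + ".log.csv")
    except FileNotFoundError:
        log = pd.DataFrame()
    return TrainedModel(
        config=config, template=template, encoders=encoders,
        decoders=decoders, vertex_mean=vertex_mean, scale=scale,
        layout=LatentLayout(config.n_regions, d), training_log=log,
        _region_idx=region_idx, _smoother=_boundary_smoother(template),
    )


def population_deviation(meshes, template: Template) -> float:
    """Mean per-vertex distance (mm) of a population from the template."""
    devs = [
        np.linalg.norm(m.vertices - template.mesh.vertices, axis=1).mean()
        for m in meshes
    ]
    return float(np.mean(devs))
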