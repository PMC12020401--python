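"""Gaussian latent-space statistics: class distributions, Mahalanobis
geometry, QDA diagnosis, and the 2D LDA manifold projection.

Latent vectors of each diagnostic class are modelled as Gaussians with their
own covariance (the QDA assumption).  Distances in latent space are measured
with the Mahalanobis distance under the healthy covariance,

    d_M(z1, z2) = sqrt((z1 - z2)^T Sigma^-1 (z1 - z2)),

which is measured in standard deviations of that distribution: two vectors
with d_M = 1 sit one SD apart.  (The raw quadratic form without the inverse
is also exposed for comparison, but has no SD calibration.)  Covariances are
regularized by shrinkage toward a scaled identity so that small per-region
sample sizes cannot produce singular fits.

LDA is used only for 2D visualization of the class manifold; QDA does the
classifying.  The 2D projection never enters the outcome metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from sklearn.covariance import ledoit_wolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from cranioshape.latent import LatentLayout


# ---------------------------------------------------------------------------
# class distributions


def regularize_covariance(
    cov: np.ndarray, eps: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Add a ridge ``eps * trace/dim * I``, escalating (x10) until the matrix
    is positive definite.  Returns the regularized matrix and the ridge used."""
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    scale = max(np.trace(cov) / p, 1e-300)
    ridge = eps * scale
    for _ in range(60):
        reg = cov + ridge * np.eye(p)
        if np.linalg.eigvalsh(reg).min() > 0:
            return reg, ridge
        ridge *= 10.0
    raise np.linalg.LinAlgError("could not regularize covariance to PD")


@dataclass
class ClassDistribution:
    """Gaussian fit of one class in the full R x d latent space.

    Per-region distributions are the d x d diagonal blocks of the global fit,
    accessible through :meth:`region`.
    """

    label: str
    mean: np.ndarray
    cov: np.ndarray
    layout: LatentLayout | None = None
    shrinkage: float = 0.0
    ridge: float = 0.0
    n_samples: int = 0
    _cho: tuple = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        p = self.mean.size
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.size

    def _factor(self):
        if self._cho is None:
            object.__setattr__(self, "_cho", cho_factor(self.cov, lower=True))
        return self._cho

    def region(self, r: int) -> "ClassDistribution":
        """d-dimensional marginal for region ``r`` (block extraction)."""
        if self.layout is None:
            raise ValueError("distribution has no region layout")
        s = self.layout.region_slice(r)
        return ClassDistribution(
            label=self.label, mean=self.mean[s], cov=self.cov[s, s],
            layout=None, shrinkage=self.shrinkage, ridge=self.ridge,
            n_samples=self.n_samples,
        )

    def log_density(self, z: np.ndarray) -> float:
        z = np.asarray(z, dtype=float).ravel()
        c, low = self._factor()
        d = z - self.mean
        maha2 = float(d @ cho_solve((c, low), d))
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        return -0.5 * (maha2 + logdet + self.dim * np.log(2.0 * np.pi))


def latent_matrix(latents: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Extract the z_* columns (or pass an array through)."""
    if isinstance(latents, pd.DataFrame):
        cols = sorted(c for c in latents.columns if c.startswith("z_"))
        if not cols:
            raise ValueError("no z_* latent columns in table")
        return latents[cols].to_numpy(dtype=float)
    return np.asarray(latents, dtype=float)


def fit_class_distributions(
    latents: pd.DataFrame | np.ndarray,
    labels,
    layout: LatentLayout | None = None,
    shrinkage: float | str = "auto",
    eps: float = 1e-6,
) -> dict[str, ClassDistribution]:
    """Fit one regularized Gaussian per class.

    ``shrinkage``: a scalar in [0, 1] mixes the sample covariance with a
    scaled identity; ``"auto"`` uses the Ledoit-Wolf estimate.  A small ridge
    (``eps``, escalated automatically if needed) guarantees positive
    definiteness even for degenerate classes.
    """
    Z = latent_matrix(latents)
    labels = np.asarray(labels)
    p = Z.shape[1]
    if layout is not None and layout.total_width != p:
        raise ValueError("layout width does not match latent dimension")
    dists: dict[str, ClassDistribution] = {}
    for cls in sorted(set(labels.tolist())):
        Zc = Z[labels == cls]
        if len(Zc) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mean = Zc.mean(axis=0)
        if shrinkage == "auto":
            cov, s = ledoit_wolf(Zc)
        else:
            s = float(shrinkage)
            if not 0.0 <= s <= 1.0:
                raise ValueError("shrinkage must be in [0, 1]")
            samp = np.cov(Zc, rowvar=False)
            samp = np.atleast_2d(samp)
            cov = (1.0 - s) * samp + s * (np.trace(samp) / p) * np.eye(p)
        cov, ridge = regularize_covariance(cov, eps)
        dists[cls] = ClassDistribution(
            label=cls, mean=mean, cov=cov, layout=layout,
            shrinkage=float(s), ridge=ridge, n_samples=len(Zc),
        )
    return dists


# ---------------------------------------------------------------------------
# Mahalanobis geometry


def _as_cov(dist: ClassDistribution | np.ndarray) -> np.ndarray:
    if isinstance(dist, ClassDistribution):
        return dist.cov
    return np.asarray(dist, dtype=float)


def mahalanobis(
    z1: np.ndarray, z2: np.ndarray, dist: ClassDistribution | np.ndarray
) -> float:
    """d_M(z1, z2) under the distribution's (inverse) covariance, in SD."""
    z1 = np.asarray(z1, dtype=float).ravel()
    z2 = np.asarray(z2, dtype=float).ravel()
    cov = _as_cov(dist)
    if z1.shape != z2.shape or cov.shape != (z1.size, z1.size):
        raise ValueError("dimension mismatch")
    d = z1 - z2
    if isinstance(dist, ClassDistribution):
        c = dist._factor()
    else:
        c = cho_factor(cov, lower=True)
    m2 = float(d @ cho_solve(c, d))
    return float(np.sqrt(max(m2, 0.0)))


def quadratic_form_raw(
    z1: np.ndarray, z2: np.ndarray, dist: ClassDistribution | np.ndarray
) -> float:
    """The literal quadratic form (z1-z2) Sigma (z1-z2)^T — no inverse, no
    square root.  Kept for comparison; it is not SD-calibrated."""
    d = np.asarray(z1, dtype=float).ravel() - np.asarray(z2, dtype=float).ravel()
    return float(d @ _as_cov(dist) @ d)


def whitening_matrix(dist: ClassDistribution | np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of the covariance."""
    cov = _as_cov(dist)
    vals, vecs = eigh(cov)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def whiten(
    z: np.ndarray,
    dist: ClassDistribution,
    region: int | None = None,
) -> np.ndarray:
    """Map ``z`` to the whitened frame of ``dist`` (optionally a region's
    marginal): ``w = Sigma^{-1/2} (z - mu)``; ``|w|`` equals d_M(z, mu)."""
    d = dist.region(region) if region is not None else dist
    z = np.asarray(z, dtype=float).ravel()
    if z.size != d.dim:
        raise ValueError("dimension mismatch")
    return whitening_matrix(d) @ (z - d.mean)


# ---------------------------------------------------------------------------
# discriminant analysis


def qda_predict(
    dists: dict[str, ClassDistribution],
    z: np.ndarray,
    priors: dict[str, float] | None = None,
) -> tuple[str, dict[str, float]]:
    """Classify one latent vector with class-specific Gaussians.

    Returns the maximum-posterior label (ties broken by class-name order) and
    the normalized posteriors.  Priors default to uniform: augmented class
    sizes reflect augmentation policy, not prevalence.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 fitted classes")
    classes = sorted(dists)
    if priors is None:
        priors = {c: 1.0 / len(classes) for c in classes}
    scores = np.array(
        [dists[c].log_density(z) + np.log(priors[c]) for c in classes]
    )
    scores -= scores.max()
    post = np.exp(scores)
    post /= post.sum()
    label = classes[int(np.argmax(post))]
    return label, dict(zip(classes, post.tolist()))


def qda_predict_batch(
    dists: dict[str, ClassDistribution],
    latents: pd.DataFrame | np.ndarray,
    priors: dict[str, float] | None = None,
) -> np.ndarray:
    Z = latent_matrix(latents)
    return np.array([qda_predict(dists, z, priors)[0] for z in Z])


@dataclass
class ConfusionMatrix:
    """Counts of (true, predicted) pairs with per-class precision."""

    counts: pd.DataFrame            # rows: true, cols: predicted
    precision: dict[str, float | None]

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion_and_precision(
    true_labels, predicted_labels, classes: list[str] | None = None
) -> ConfusionMatrix:
    """Confusion counts and per-class precision TP / (TP + FP).

    Classes never predicted have undefined precision and are reported as
    ``None`` rather than zero-filled.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    observed = set(t.tolist()) | set(p.tolist())
    if classes is None:
        classes = sorted(observed)
    elif not observed <= set(classes):
        raise ValueError(f"labels outside the fitted class set {classes}")
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for ti, pi in zip(t, p):
        counts.loc[ti, pi] += 1
    precision: dict[str, float | None] = {}
    for c in classes:
        denom = int(counts[c].sum())
        precision[c] = float(counts.loc[c, c]) / denom if denom else None
    return ConfusionMatrix(counts, precision)


@dataclass
class ManifoldProjection:
    """Frozen 2D linear-discriminant projection of the latent manifold.

    With three classes the discriminant space is exactly 2D; with two classes
    the single discriminant axis is padded with a declared zero second axis.
    Per-class 2D means and covariances are stored for contour drawing.
    """

    lda: LinearDiscriminantAnalysis
    classes: list[str]
    padded: bool
    class_means_2d: dict[str, np.ndarray]
    class_covs_2d: dict[str, np.ndarray]

    def project(self, points: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = latent_matrix(points)
        if X.ndim == 1:
            X = X[None, :]
        Y = self.lda.transform(X)
        if self.padded:
            Y = np.column_stack([Y[:, 0], np.zeros(len(Y))])
        return Y[:, :2]


def lda_fit_project(
    latents: pd.DataFrame | np.ndarray,
    labels,
    new_points: pd.DataFrame | np.ndarray | None = None,
) -> tuple[ManifoldProjection, np.ndarray]:
    """Fit the LDA projection on labelled latents; project new points with
    the frozen transform (never refit on pre/post-operative data)."""
    Z = latent_matrix(latents)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for a projection")
    n_comp = min(2, len(classes) - 1, Z.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_comp, solver="svd")
    lda.fit(Z, labels)
    padded = n_comp == 1
    proj = ManifoldProjection(lda, classes, padded, {}, {})
    Y_train = proj.project(Z)
    for c in classes:
        Yc = Y_train[labels == c]
        proj.class_means_2d[c] = Yc.mean(axis=0)
        proj.class_covs_2d[c] = np.atleast_2d(np.cov(Yc, rowvar=False))
    coords = proj.project(new_points) if new_points is not None else Y_train
    return proj, coords
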