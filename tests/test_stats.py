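"""Gaussian fits, Mahalanobis geometry, QDA, confusion counts, LDA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from cranioshape import stats as st
from cranioshape.latent import LatentLayout


def _random_pd(rng, dim):
    a = rng.normal(size=(dim, dim))
    return a @ a.T + dim * np.eye(dim) * 0.1


# ---------------------------------------------------------------------------
# class distributions


def test_degenerate_class_gets_floor_covariance():
    z = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0], [3.5, 4.5]])
    labels = np.array(["dup", "dup", "var", "var"])
    dists = st.fit_class_distributions(z, labels, shrinkage=0.5)
    dup = dists["dup"]
    assert np.allclose(dup.mean, [1.0, 2.0])
    assert np.linalg.eigvalsh(dup.cov).min() > 0


def test_fit_recovers_known_gaussian_within_three_se(rng):
    mean = np.array([1.0, -2.0, 0.5])
    cov = np.diag([4.0, 1.0, 0.25])
    z = rng.multivariate_normal(mean, cov, size=4000)
    dists = st.fit_class_distributions(
        z, np.repeat("c", len(z)), shrinkage=0.0
    )
    se = np.sqrt(np.diag(cov) / len(z))
    assert np.all(np.abs(dists["c"].mean - mean) < 3 * se)


def test_regional_covariance_is_diagonal_block(rng):
    layout = LatentLayout(3, 2)
    z = rng.normal(size=(50, 6))
    dists = st.fit_class_distributions(
        z, np.repeat("c", 50), layout=layout, shrinkage=0.0
    )
    full = dists["c"]
    for r in (1, 2, 3):
        sl = layout.region_slice(r)
        reg = full.region(r)
        assert np.allclose(reg.cov, full.cov[sl, sl])
        assert np.allclose(reg.mean, full.mean[sl])


def test_fit_rejects_singleton_class():
    z = np.zeros((3, 2))
    with pytest.raises(ValueError):
        st.fit_class_distributions(z, np.array(["a", "a", "b"]))


# ---------------------------------------------------------------------------
# Mahalanobis distance and whitening


def test_mahalanobis_reduces_to_euclidean_under_identity():
    assert st.mahalanobis([0, 0], [3, 4], np.eye(2)) == pytest.approx(5.0)


def test_one_sd_apart_has_unit_distance():
    # variance 4 along the first axis: a separation of 2 is exactly one SD
    assert st.mahalanobis([0, 0], [2, 0], np.diag([4.0, 1.0])) == pytest.approx(1.0)


def test_mahalanobis_agrees_with_whitening_oracle(rng):
    for _ in range(25):
        cov = _random_pd(rng, 5)
        z1, z2 = rng.normal(size=5), rng.normal(size=5)
        vals, vecs = np.linalg.eigh(cov)
        w = (vecs / np.sqrt(vals)) @ vecs.T
        oracle = float(np.linalg.norm(w @ (z1 - z2)))
        assert st.mahalanobis(z1, z2, cov) == pytest.approx(oracle, abs=1e-8)


@settings(deadline=None, max_examples=25)
@given(hst.integers(0, 2**31 - 1))
def test_mahalanobis_is_a_metric_on_random_triples(seed):
    rng = np.random.default_rng(seed)
    cov = _random_pd(rng, 4)
    x, y, z = rng.normal(size=(3, 4))
    dxy = st.mahalanobis(x, y, cov)
    assert dxy == pytest.approx(st.mahalanobis(y, x, cov))
    assert st.mahalanobis(x, x, cov) == pytest.approx(0.0, abs=1e-12)
    assert dxy <= st.mahalanobis(x, z, cov) + st.mahalanobis(z, y, cov) + 1e-9


def test_mahalanobis_scale_equivariance(rng):
    cov = _random_pd(rng, 3)
    z1, z2 = rng.normal(size=3), rng.normal(size=3)
    c = 7.3
    assert st.mahalanobis(c * z1, c * z2, c**2 * cov) == pytest.approx(
        st.mahalanobis(z1, z2, cov)
    )


def test_whiten_zero_at_mean_and_norm_consistency(rng):
    cov = _random_pd(rng, 4)
    mean = rng.normal(size=4)
    dist = st.ClassDistribution("h", mean, cov)
    assert np.allclose(st.whiten(mean, dist), 0.0)
    for _ in range(5):
        z = rng.normal(size=4)
        assert np.linalg.norm(st.whiten(z, dist)) == pytest.approx(
            st.mahalanobis(z, mean, dist), abs=1e-8
        )


def test_whiten_identity_covariance_is_centering(rng):
    dist = st.ClassDistribution("h", np.array([1.0, 2.0]), np.eye(2))
    z = np.array([4.0, 6.0])
    assert np.allclose(st.whiten(z, dist), [3.0, 4.0])


def test_raw_quadratic_form_uses_covariance_not_inverse():
    cov = np.diag([4.0, 1.0])
    # the literal printed form has no SD calibration: (2,0) yields 16, not 1
    assert st.quadratic_form_raw([0, 0], [2, 0], cov) == pytest.approx(16.0)


# ---------------------------------------------------------------------------
# QDA


def _two_class_dists():
    a = st.ClassDistribution("a", np.zeros(2), np.eye(2))
    b = st.ClassDistribution("b", np.array([3.0, 0.0]), np.eye(2))
    return {"a": a, "b": b}


def test_qda_label_at_class_mean():
    dists = _two_class_dists()
    label, post = st.qda_predict(dists, np.zeros(2))
    assert label == "a"
    assert post["a"] > post["b"]


def test_qda_posteriors_normalize(rng):
    dists = _two_class_dists()
    for _ in range(10):
        _, post = st.qda_predict(dists, rng.normal(size=2))
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


def test_qda_boundary_matches_closed_form_1d():
    # unequal variances: boundary where log-densities are equal
    s1, s2, m1, m2 = 1.0, 2.0, 0.0, 4.0
    a = st.ClassDistribution("a", [m1], [[s1**2]])
    b = st.ClassDistribution("b", [m2], [[s2**2]])
    # solve -x^2/2 - log(s1) = -(x-4)^2/8 - log(s2) for x in (0, 4)
    coeffs = [-1 / 2 + 1 / 8, -1.0, 2.0 + np.log(s2 / s1)]
    roots = np.roots(coeffs)
    x_star = roots[(roots > m1) & (roots < m2)][0].real
    for dx, expect in ((-1e-6, "a"), (1e-6, "b")):
        label, _ = st.qda_predict({"a": a, "b": b}, [x_star + dx])
        assert label == expect


def test_qda_shared_covariance_reduces_to_nearest_mahalanobis_mean(rng):
    cov = _random_pd(rng, 3)
    means = {"a": rng.normal(size=3), "b": rng.normal(size=3),
             "c": rng.normal(size=3)}
    dists = {k: st.ClassDistribution(k, m, cov) for k, m in means.items()}
    for _ in range(20):
        z = rng.normal(size=3, scale=2.0)
        label, _ = st.qda_predict(dists, z)
        nearest = min(means, key=lambda k: st.mahalanobis(z, means[k], cov))
        assert label == nearest


def test_qda_agrees_with_sklearn_oracle(rng):
    X = np.vstack([
        rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 2]], size=60),
        rng.multivariate_normal([2.5, 1], [[2, -0.4], [-0.4, 0.5]], size=60),
    ])
    y = np.repeat(["a", "b"], 60)
    dists = st.fit_class_distributions(X, y, shrinkage=0.0, eps=1e-12)
    sk = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5], store_covariance=True)
    sk.fit(X, y)
    Xt = rng.normal(size=(50, 2), scale=2.0)
    ours = st.qda_predict_batch(dists, Xt)
    assert np.mean(ours == sk.predict(Xt)) > 0.98


# ---------------------------------------------------------------------------
# confusion matrix


def test_confusion_perfect_prediction():
    cm = st.confusion_and_precision(["a", "b", "b"], ["a", "b", "b"])
    assert cm.precision == {"a": 1.0, "b": 1.0}


def test_confusion_toy_precision():
    true = ["A"] * 9 + ["B"]
    pred = ["A"] * 10
    cm = st.confusion_and_precision(true, pred)
    assert cm.precision["A"] == pytest.approx(0.9)
    assert cm.precision["B"] is None  # never predicted: undefined, flagged


@settings(deadline=None, max_examples=20)
@given(hst.integers(0, 2**31 - 1))
def test_confusion_counts_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    classes = ["x", "y", "z"]
    true = rng.choice(classes, size=40)
    pred = rng.choice(classes, size=40)
    cm = st.confusion_and_precision(true, pred, classes=classes)
    for t in classes:
        for p in classes:
            brute = sum(1 for a, b in zip(true, pred) if a == t and b == p)
            assert cm.counts.loc[t, p] == brute
    assert cm.n_total == 40
    for c, prec in cm.precision.items():
        if prec is not None:
            assert 0.0 <= prec <= 1.0


def test_confusion_rejects_unknown_label():
    with pytest.raises(ValueError):
        st.confusion_and_precision(["a"], ["q"], classes=["a", "b"])


# ---------------------------------------------------------------------------
# LDA projection


def _three_class_latents(rng, n=40):
    means = {"a": [0, 0, 0, 0], "b": [6, 0, 0, 0], "c": [0, 6, 0, 0]}
    X = np.vstack([
        rng.multivariate_normal(m, np.eye(4), size=n) for m in means.values()
    ])
    y = np.repeat(list(means), n)
    return X, y


def test_lda_three_classes_gives_exactly_two_axes(rng):
    X, y = _three_class_latents(rng)
    proj, coords = st.lda_fit_project(X, y)
    assert coords.shape == (len(X), 2)
    assert not proj.padded


def test_lda_separates_well_separated_classes(rng):
    X, y = _three_class_latents(rng)
    proj, coords = st.lda_fit_project(X, y)
    y = np.asarray(y)
    scatter = np.mean([
        np.linalg.norm(coords[y == c] - proj.class_means_2d[c], axis=1).mean()
        for c in proj.classes
    ])
    for i, a in enumerate(proj.classes):
        for b in proj.classes[i + 1:]:
            gap = np.linalg.norm(
                proj.class_means_2d[a] - proj.class_means_2d[b]
            )
            assert gap > 2 * scatter


def test_lda_projection_is_deterministic_and_frozen(rng):
    X, y = _three_class_latents(rng)
    proj, _ = st.lda_fit_project(X, y)
    p1 = proj.project(X[:5])
    p2 = proj.project(X[:5])
    assert np.array_equal(p1, p2)


def test_lda_two_classes_pads_second_axis(rng):
    X = np.vstack([rng.normal(size=(20, 3)), rng.normal(3.0, size=(20, 3))])
    y = np.repeat(["a", "b"], 20)
    proj, coords = st.lda_fit_project(X, y)
    assert proj.padded
    assert coords.shape == (40, 2)
    assert np.all(coords[:, 1] == 0.0)
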