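"""Synthetic template, populations, surgery simulation, latent fixtures."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from cranioshape import synthetic as syn
from cranioshape.latent import LatentLayout
from cranioshape.mesh import region_vertices, vertex_adjacency


def test_template_is_deterministic(template3):
    again = syn.make_template(3, seed=0)
    assert np.array_equal(template3.mesh.vertices, again.mesh.vertices)
    assert np.array_equal(template3.partition.labels, again.partition.labels)


def test_template_vertex_and_face_counts_follow_subdivision(template3):
    # subdivided icosahedron: V = 10 * 4**n + 2, F = 20 * 4**n
    assert template3.mesh.n_vertices == 642
    assert template3.mesh.n_faces == 1280


def test_template_regions_nonempty_and_contiguous(template3):
    adj = vertex_adjacency(template3.mesh.faces, template3.mesh.n_vertices)
    for r in range(1, template3.n_regions + 1):
        idx = region_vertices(template3.partition, r)
        assert len(idx) > 0
        sub = adj[np.ix_(idx, idx)]
        n_comp, _ = connected_components(sp.csr_matrix(sub), directed=False)
        assert n_comp == 1, f"region {r} is not contiguous"


def test_population_zero_individual_sd_collapses_classes(template2):
    spec = syn.PopulationSpec(
        n_per_class={"healthy": 3, "synA": 3, "synB": 3}, individual_sd=0.0,
        seed=5,
    )
    subs = syn.sample_population(spec, template2)
    by_class = {}
    for s in subs:
        by_class.setdefault(s.class_label, []).append(s.mesh.vertices)
    for cls, meshes in by_class.items():
        for v in meshes[1:]:
            assert np.array_equal(v, meshes[0])
    # healthy carries no class offset: it reproduces the template exactly
    assert np.allclose(by_class["healthy"][0], template2.mesh.vertices)


def test_class_separation_exceeds_within_class_scatter(template3, pop_spec):
    subs = syn.sample_population(pop_spec, template3)
    by_class = {}
    for s in subs:
        by_class.setdefault(s.class_label, []).append(s.mesh.vertices)

    def rms(a, b):
        return np.sqrt(((a - b) ** 2).sum(axis=1).mean())

    intra = np.mean(
        [
            rms(vs[i], vs[j])
            for vs in by_class.values()
            for i in range(5)
            for j in range(i + 1, 5)
        ]
    )
    inter = np.mean(
        [rms(a, b) for a in by_class["healthy"][:5] for b in by_class["synA"][:5]]
    )
    assert inter > intra


def test_class_offsets_are_localized_to_their_regions(template3, pop_spec):
    offsets = syn.class_offset_fields(pop_spec, template3)
    for cls in ("synA", "synB"):
        field = offsets[cls]
        idx = np.concatenate(
            [
                region_vertices(template3.partition, r)
                for r in pop_spec.region_effects[cls]
            ]
        )
        frac = (field[idx] ** 2).sum() / (field**2).sum()
        assert frac >= 0.9, f"{cls}: only {frac:.2f} of energy inside regions"


def test_surgery_alpha_zero_is_identity(template3, pop_spec):
    subs = syn.sample_population(pop_spec, template3)
    healthy_mean = syn.class_mean_mesh(subs, "healthy")
    patient = next(s for s in subs if s.class_label == "synA")
    spec = syn.SurgerySpec((5, 6), completeness=0.0, noise_sd=0.0)
    post = syn.apply_surgery(patient, spec, healthy_mean, template3)
    assert np.array_equal(post.mesh.vertices, patient.mesh.vertices)
    assert post.stage == "post"


def test_surgery_full_completeness_all_regions_reaches_healthy_mean(
    template3, pop_spec
):
    subs = syn.sample_population(pop_spec, template3)
    healthy_mean = syn.class_mean_mesh(subs, "healthy")
    patient = next(s for s in subs if s.class_label == "synA")
    spec = syn.SurgerySpec(
        tuple(range(1, 16)), completeness=1.0, noise_sd=0.0
    )
    post = syn.apply_surgery(patient, spec, healthy_mean, template3)
    assert np.abs(post.mesh.vertices - healthy_mean.vertices).max() < 1e-9


@pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75, 1.0])
def test_surgery_scales_distance_to_healthy_by_one_minus_alpha(
    template3, pop_spec, alpha
):
    subs = syn.sample_population(pop_spec, template3)
    healthy_mean = syn.class_mean_mesh(subs, "healthy")
    patient = next(s for s in subs if s.class_label == "synB")
    targets = (1, 2)
    post = syn.apply_surgery(
        patient, syn.SurgerySpec(targets, alpha, noise_sd=0.0),
        healthy_mean, template3,
    )
    idx = np.concatenate(
        [region_vertices(template3.partition, r) for r in targets]
    )
    d_pre = np.linalg.norm(patient.mesh.vertices - healthy_mean.vertices, axis=1)
    d_post = np.linalg.norm(post.mesh.vertices - healthy_mean.vertices, axis=1)
    assert np.allclose(d_post[idx], (1.0 - alpha) * d_pre[idx], atol=1e-9)


def test_adverse_surgery_increases_distance_on_targets(template3, pop_spec):
    subs = syn.sample_population(pop_spec, template3)
    healthy_mean = syn.class_mean_mesh(subs, "healthy")
    patient = next(s for s in subs if s.class_label == "synA")
    targets = (5, 6)
    post = syn.apply_surgery(
        patient,
        syn.SurgerySpec(targets, 0.5, direction_mode="away_from_healthy"),
        healthy_mean, template3,
    )
    idx = np.concatenate(
        [region_vertices(template3.partition, r) for r in targets]
    )
    d_pre = np.linalg.norm(patient.mesh.vertices - healthy_mean.vertices, axis=1)
    d_post = np.linalg.norm(post.mesh.vertices - healthy_mean.vertices, axis=1)
    assert np.all(d_post[idx] >= d_pre[idx])


def test_surgery_requires_targets_and_valid_mode():
    with pytest.raises(ValueError):
        syn.SurgerySpec(()).validate()
    with pytest.raises(ValueError):
        syn.SurgerySpec((1,), direction_mode="sideways").validate()


def _fixture_spec(scale=1.0, n=5, seed=9):
    layout = LatentLayout(2, 2)
    rng = np.random.default_rng(41)
    means = {"healthy": np.zeros(4), "synA": rng.normal(size=4)}
    covs = {c: scale * np.eye(4) for c in means}
    return syn.LatentFixtureSpec(
        means, covs, {c: n for c in means}, layout, seed=seed
    )


def test_latent_fixture_tiny_covariance_collapses_to_mean():
    spec = _fixture_spec(scale=1e-12)
    table = syn.sample_latent_fixture(spec)
    z = table[table.class_label == "synA"][["z_001", "z_002", "z_003", "z_004"]]
    assert np.abs(z.to_numpy() - spec.means["synA"]).max() < 1e-4


def test_latent_fixture_is_deterministic_and_mean_consistent():
    spec = _fixture_spec(n=10000)
    t1 = syn.sample_latent_fixture(spec)
    t2 = syn.sample_latent_fixture(spec)
    assert t1.equals(t2)
    z = t1[t1.class_label == "synA"].filter(like="z_").to_numpy()
    se = z.std(axis=0, ddof=1) / np.sqrt(len(z))
    assert np.all(np.abs(z.mean(axis=0) - spec.means["synA"]) < 3 * se + 1e-12)


def test_latent_fixture_rejects_non_pd_covariance():
    spec = _fixture_spec()
    spec.covs["synA"] = -np.eye(4)
    with pytest.raises(ValueError):
        syn.sample_latent_fixture(spec)


def test_population_draw_seed_changes_draws_not_structure(template2, pop_spec):
    spec = dataclasses.replace(
        pop_spec, n_per_class={"healthy": 2, "synA": 2, "synB": 2}
    )
    a = syn.sample_population(spec, template2)
    b = syn.sample_population(spec, template2, draw_seed=99)
    assert not np.allclose(a[0].mesh.vertices, b[0].mesh.vertices)
    # same class offsets underneath: class means with individual_sd -> 0
    spec0 = dataclasses.replace(spec, individual_sd=0.0)
    c = syn.sample_population(spec0, template2)
    d = syn.sample_population(spec0, template2, draw_seed=99)
    assert np.allclose(c[2].mesh.vertices, d[2].mesh.vertices)
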