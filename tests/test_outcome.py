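"""Versors, the regional outcome metric m_r, patient and cohort reports."""

import numpy as np
import pytest

from cranioshape import autoencoder as ae
from cranioshape import outcome as oc
from cranioshape import stats as st
from cranioshape import synthetic as syn
from cranioshape.latent import LatentLayout, LatentVector


def _identity_dist(dim=2, mean=None):
    mean = np.zeros(dim) if mean is None else np.asarray(mean, float)
    return st.ClassDistribution("healthy", mean, np.eye(dim))


def _pair(pre, post, n_regions=1):
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    layout = LatentLayout(n_regions, pre.size // n_regions)
    return oc.SurgicalPair(
        "p1", "proc", LatentVector(pre, layout), LatentVector(post, layout)
    )


# ---------------------------------------------------------------------------
# versors


def test_surgical_versor_normalizes_movement():
    v, null = oc.surgical_versor([0, 0], [0, 3], _identity_dist())
    assert not null
    assert np.allclose(v, [0, 1])
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


def test_surgical_versor_null_when_no_movement():
    v, null = oc.surgical_versor([1, 2], [1, 2], _identity_dist())
    assert null
    assert np.all(v == 0)


def test_healthy_versor_points_to_mean():
    v, null = oc.healthy_versor([4, 0], _identity_dist())
    assert not null
    assert np.allclose(v, [-1, 0])


def test_healthy_versor_null_at_mean():
    v, null = oc.healthy_versor([0, 0], _identity_dist())
    assert null


# ---------------------------------------------------------------------------
# the regional metric: worked cases


def test_metric_is_one_for_halving_distance_straight_toward_mean():
    out = oc.regional_metric(_pair([2, 0], [1, 0]), 1, _identity_dist())
    assert out.magnitude == pytest.approx(1.0)
    assert out.proximity == pytest.approx(1.0)
    assert out.alignment == pytest.approx(1.0)
    assert out.m_r == pytest.approx(1.0)


def test_metric_is_minus_one_third_for_moving_straight_away():
    out = oc.regional_metric(_pair([2, 0], [3, 0]), 1, _identity_dist())
    assert out.magnitude == pytest.approx(1.0)
    assert out.proximity == pytest.approx(3.0)
    assert out.alignment == pytest.approx(-1.0)
    assert out.m_r == pytest.approx(-1.0 / 3.0)


def test_metric_zero_with_flag_when_no_movement():
    out = oc.regional_metric(_pair([2, 0], [2, 0]), 1, _identity_dist())
    assert out.m_r == 0.0
    assert out.no_movement


def test_metric_floors_denominator_at_healthy_mean():
    out = oc.regional_metric(_pair([2, 0], [0, 0]), 1, _identity_dist(),
                             eps=1e-6)
    assert out.denominator_floored
    assert out.m_r == pytest.approx(2.0 / 1e-6)


def test_metric_product_form_switch():
    out = oc.regional_metric(_pair([2, 0], [1, 0]), 1, _identity_dist(),
                             form="product")
    assert out.m_r == pytest.approx(1.0 * 1.0 * 1.0)
    out2 = oc.regional_metric(_pair([2, 0], [3, 0]), 1, _identity_dist(),
                              form="product")
    assert out2.m_r == pytest.approx(-3.0)


def test_metric_monotone_in_completeness_on_ideal_ray():
    pre = np.array([2.0, 0.0])
    values = []
    for alpha in (0.2, 0.4, 0.6, 0.8):
        post = pre * (1 - alpha)
        values.append(oc.regional_metric(_pair(pre, post), 1,
                                         _identity_dist()).m_r)
        # closed form on the ideal ray: alpha / (1 - alpha)
        assert values[-1] == pytest.approx(alpha / (1 - alpha))
    assert np.all(np.diff(values) > 0)


def test_metric_invariant_under_linear_reparametrization(rng):
    """d_M, alignment and m_r are properties of the distribution geometry:
    any common invertible linear map of latents and covariance leaves them
    unchanged."""
    dim = 5
    a = rng.normal(size=(dim, dim))
    cov = a @ a.T + 0.5 * np.eye(dim)
    mean = rng.normal(size=dim)
    pre, post = rng.normal(size=dim, scale=3), rng.normal(size=dim, scale=3)
    T = rng.normal(size=(dim, dim)) + 2 * np.eye(dim)  # invertible w.h.p.
    d0 = st.ClassDistribution("healthy", mean, cov)
    d1 = st.ClassDistribution("healthy", T @ mean, T @ cov @ T.T)
    o0 = oc.regional_metric(_pair(pre, post), 1, d0)
    o1 = oc.regional_metric(_pair(T @ pre, T @ post), 1, d1)
    assert o1.magnitude == pytest.approx(o0.magnitude, abs=1e-8)
    assert o1.proximity == pytest.approx(o0.proximity, abs=1e-8)
    assert o1.alignment == pytest.approx(o0.alignment, abs=1e-8)
    assert o1.m_r == pytest.approx(o0.m_r, abs=1e-8)


# ---------------------------------------------------------------------------
# patient assessment (end-to-end on the synthetic study)


def _surgical_pair(e2e, targets, alpha, mode="toward_healthy", patient_idx=0):
    patients = [s for s in e2e["held"] if s.class_label == "synA"]
    patient = patients[patient_idx]
    spec = syn.SurgerySpec(targets, alpha, direction_mode=mode, noise_sd=0.0)
    post = syn.apply_surgery(patient, spec, e2e["healthy_mean"],
                             e2e["template"])
    return patient, post, oc.SurgicalPair(
        patient.subject_id, "test_proc",
        ae.encode(e2e["model"], patient.mesh),
        ae.encode(e2e["model"], post.mesh),
    )


def test_assess_patient_null_surgery_gives_all_zero(e2e):
    z = ae.encode(e2e["model"], e2e["held"][0].mesh)
    pair = oc.SurgicalPair("p", "none", z, z)
    rep = oc.assess_patient(pair, e2e["dists"])
    assert all(ro.m_r == 0.0 and ro.no_movement for ro in rep.regional)
    assert rep.global_dm_pre == pytest.approx(rep.global_dm_post)


def test_assess_patient_targeted_regions_dominate(e2e):
    targets = (5, 6)
    _, _, pair = _surgical_pair(e2e, targets, 0.5)
    rep = oc.assess_patient(pair, e2e["dists"])
    m = {ro.region: ro.m_r for ro in rep.regional}
    for r in targets:
        assert m[r] > 0.5
    off = max(abs(m[r]) for r in m if r not in targets)
    assert off < 0.5 * min(m[r] for r in targets)
    assert rep.global_dm_post < rep.global_dm_pre


def test_adverse_surgery_yields_negative_metric(e2e):
    targets = (5, 6)
    _, _, pair = _surgical_pair(e2e, targets, 0.5, mode="away_from_healthy")
    rep = oc.assess_patient(pair, e2e["dists"])
    m = {ro.region: ro.m_r for ro in rep.regional}
    for r in targets:
        assert m[r] < 0


def test_cohort_summary_single_report_medians(e2e):
    z1 = ae.encode(e2e["model"], e2e["held"][1].mesh)
    z2 = ae.encode(e2e["model"], e2e["held"][2].mesh)
    pair = oc.SurgicalPair("p", "only_proc", z1, z2)
    rep = oc.assess_patient(pair, e2e["dists"])
    summary = oc.cohort_summary([rep])
    m = {ro.region: ro.m_r for ro in rep.regional}
    for _, row in summary.iterrows():
        assert row["median"] == pytest.approx(m[row["region"]])
        assert row["n"] == 1


def test_cohort_summary_higher_completeness_scores_higher(e2e):
    targets = (5, 6)
    reports = {}
    for alpha in (0.3, 0.8):
        reps = []
        for i in range(3):
            _, _, pair = _surgical_pair(e2e, targets, alpha, patient_idx=i)
            pair = oc.SurgicalPair(pair.patient_id, f"proc_a{alpha}",
                                   pair.z_pre, pair.z_post)
            reps.append(oc.assess_patient(pair, e2e["dists"]))
        reports[alpha] = reps
    summary = oc.cohort_summary(reports[0.3] + reports[0.8])
    for r in targets:
        lo = summary[(summary.procedure_label == "proc_a0.3")
                     & (summary.region == r)]["median"].iloc[0]
        hi = summary[(summary.procedure_label == "proc_a0.8")
                     & (summary.region == r)]["median"].iloc[0]
        assert hi > lo


def test_untargeted_region_stays_quiet_across_cohort(e2e):
    """Analogue of a subcranial procedure leaving the supraorbital and
    frontal regions unchanged: regions never targeted must score near zero."""
    targets = (5, 6, 9)
    untouched = (1, 2)
    reps = []
    for i in range(3):
        _, _, pair = _surgical_pair(e2e, targets, 0.7, patient_idx=i)
        reps.append(oc.assess_patient(pair, e2e["dists"]))
    summary = oc.cohort_summary(reps)
    target_medians = summary[summary.region.isin(targets)]["median"]
    quiet = summary[summary.region.isin(untouched)]["median"].abs()
    assert quiet.max() < 0.5 * target_medians.min()


def test_cohort_summary_requires_reports():
    with pytest.raises(ValueError):
        oc.cohort_summary([])


def test_pair_layout_mismatch_rejected():
    a = LatentVector(np.zeros(4), LatentLayout(2, 2))
    b = LatentVector(np.zeros(6), LatentLayout(2, 3))
    with pytest.raises(ValueError):
        oc.SurgicalPair("p", "x", a, b)
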