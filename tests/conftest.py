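"""Shared fixtures.

``e2e`` is the expensive session fixture: the full synthetic study at its
default conditions (three classes of 30 subjects, spectral augmentation to
100 per class, toy autoencoder training, latent encoding and Gaussian fits).
Model-dependent tests all share it so training happens once per session.
"""

import numpy as np
import pytest

from cranioshape import autoencoder as ae
from cranioshape import spectral as spc
from cranioshape import stats as st
from cranioshape import synthetic as syn


@pytest.fixture(scope="session")
def template2():
    """Small head template (162 vertices) for cheap plumbing tests."""
    return syn.make_template(2, seed=0)


@pytest.fixture(scope="session")
def template3():
    """Study-scale head template (642 vertices, 15 regions)."""
    return syn.make_template(3, seed=0)


@pytest.fixture(scope="session")
def pop_spec():
    return syn.PopulationSpec(seed=1)


@pytest.fixture(scope="session")
def e2e(template3, pop_spec):
    train_subjects = syn.sample_population(pop_spec, template3)
    heldout = syn.sample_population(
        pop_spec, template3, draw_seed=2, id_prefix="ho"
    )
    augmented = spc.augment_population(
        train_subjects, 100, template3, seed=3, skip_classes=()
    )
    model = ae.train(
        [s.mesh for s in augmented], template3, ae.ModelConfig(seed=0)
    )
    lat_train = ae.encode_population(model, augmented)
    lat_held = ae.encode_population(model, heldout)
    dists = st.fit_class_distributions(
        lat_train, lat_train["class_label"], layout=model.layout
    )
    return {
        "template": template3,
        "spec": pop_spec,
        "train": train_subjects,
        "held": heldout,
        "augmented": augmented,
        "model": model,
        "lat_train": lat_train,
        "lat_held": lat_held,
        "dists": dists,
        "healthy_mean": syn.class_mean_mesh(train_subjects, "healthy"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
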