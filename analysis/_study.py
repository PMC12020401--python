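"""Shared study conditions for the numbered analysis scripts.

All scripts derive their inputs from one seed so that each can be run on its
own: earlier stages are regenerated deterministically (generation is cheap);
the trained autoencoder is cached as ``model.npz`` in the output directory.
"""

from __future__ import annotations

import os

from cranioshape import autoencoder as ae
from cranioshape import spectral as spc
from cranioshape import synthetic as syn
from cranioshape.pipeline import DEFAULT_PROCEDURES

AUGMENT_TO = 100
BASIS_K = 128
PROCEDURES = DEFAULT_PROCEDURES


def build_cohorts(seed: int):
    """Template plus training and held-out cohorts at the study conditions."""
    template = syn.make_template(3, seed=seed)
    spec = syn.PopulationSpec(seed=seed + 1)
    train = syn.sample_population(spec, template)
    held = syn.sample_population(
        spec, template, draw_seed=seed + 2, id_prefix="ho"
    )
    return template, spec, train, held


def augment(train, template, seed: int):
    return spc.augment_population(
        train, AUGMENT_TO, template, k=BASIS_K, seed=seed + 3, skip_classes=()
    )


def get_model(out_dir: str, seed: int, retrain: bool = False):
    """Load the cached autoencoder or train (and cache) it."""
    template, spec, train, held = build_cohorts(seed)
    augmented = augment(train, template, seed)
    path = os.path.join(out_dir, "model.npz")
    if os.path.exists(path) and not retrain:
        model = ae.load_model(path, template)
    else:
        model = ae.train(
            [s.mesh for s in augmented], template, ae.ModelConfig(seed=seed)
        )
        os.makedirs(out_dir, exist_ok=True)
        ae.save_model(model, path)
    return template, spec, train, held, augmented, model
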