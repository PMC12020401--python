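"""Diagnosis and manifold visualization in latent space.

Fits per-class Gaussians (QDA) on the training latents, classifies 30
held-out subjects per class, and projects the latent manifold to 2D with LDA
for the class-contour figure.
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _study import get_model  # noqa: E402

from cranioshape import autoencoder as ae  # noqa: E402
from cranioshape import stats as st  # noqa: E402
from cranioshape.plotting import plot_manifold  # noqa: E402


def main():
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=7)
    p.add_argument("--out", default="results/analysis")
    args = p.parse_args()
    os.makedirs(args.out, exist_ok=True)

    template, spec, train, held, augmented, model = get_model(
        args.out, args.seed
    )
    lat_train = ae.encode_population(model, augmented)
    lat_held = ae.encode_population(model, held)
    lat_train.to_csv(os.path.join(args.out, "latents_train.csv"), index=False)
    lat_held.to_csv(os.path.join(args.out, "latents_heldout.csv"), index=False)

    dists = st.fit_class_distributions(
        lat_train, lat_train["class_label"], layout=model.layout
    )
    pred = st.qda_predict_batch(dists, lat_held)
    cm = st.confusion_and_precision(lat_held["class_label"].to_numpy(), pred)
    print("confusion matrix (rows true, columns predicted):")
    print(cm.counts.to_string())
    print("per-class precision:",
          {k: None if v is None else round(v, 3)
           for k, v in cm.precision.items()})
    cm.counts.to_csv(os.path.join(args.out, "confusion_matrix.csv"))
    with open(os.path.join(args.out, "precision.json"), "w") as f:
        json.dump(cm.precision, f, indent=2)

    projection, _ = st.lda_fit_project(lat_train, lat_train["class_label"])
    fig = os.path.join(args.out, "manifold_classes.png")
    plot_manifold(projection, None, fig)
    print(f"2D latent manifold (LDA) written to {fig}")


if __name__ == "__main__":
    main()
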