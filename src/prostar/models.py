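"""The packaged default prediction model.

Trained once on a seeded synthetic corpus (all 20 residue types, helical
backbones, two side-chain conformers, 0.05 Å coordinate noise) and shipped
as JSON inside the package, so archives can be written and read without
any training step.  Archives embed the model fingerprint; retraining (CLI
``prostar train``) produces a model with a different fingerprint, and the
two can never be mixed.

The shipped model is trained with k capped at 4 and centroids stored at
1 mÅ precision — predictions are rounded to 1 mÅ anyway, and the cap keeps
the packaged file small and encoding fast.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .fixtures import FixtureSpec, training_tables
from .training import PredictionModel, TrainingConfig, loads_model, train_model

#: study conditions of the shipped model (regeneration recipe)
DEFAULT_CORPUS = FixtureSpec(n_structures=40, residues_per_chain=50,
                             conformer_count=2, coordinate_noise_sd=0.05,
                             seed=20240)
DEFAULT_TRAINING = TrainingConfig(k_max=4, seed=20240)


@lru_cache(maxsize=1)
def default_model() -> PredictionModel:
    text = (resources.files("prostar") / "data" / "default_model.json"
            ).read_text()
    return loads_model(text)


def train_default_model() -> PredictionModel:
    """Recompute the shipped model from its recipe (slow; training)."""
    import numpy as np
    model = train_model(training_tables(DEFAULT_CORPUS), DEFAULT_TRAINING)
    for e in model.entries.values():
        e.centroid_set.centroids = np.round(e.centroid_set.centroids, 3)
    model.invalidate()
    return model
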