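"""Train a coordinate-prediction model and inspect what it learned.

Builds a corpus with two discrete side-chain conformers per residue type,
trains the per-(residue, atom) centroid model, and prints the chosen
reference atoms and centroid counts for a few slots.  With well-separated
conformers the encoding-cost criterion selects one centroid per
conformer for the conformer-dependent slots.
"""

import warnings

warnings.filterwarnings("ignore")

from prostar import FixtureSpec, TrainingConfig, train_model
from prostar.fixtures import training_tables

spec = FixtureSpec(n_structures=8, residues_per_chain=20,
                   residue_alphabet=("ALA", "HIS", "GLU"),
                   conformer_count=2, coordinate_noise_sd=0.0,
                   seed=11, helical=False)
model = train_model(training_tables(spec), TrainingConfig(seed=11))

print(f"trained {len(model.entries)} atom slots, "
      f"fingerprint {model.fingerprint}")
for key in (("HIS", "CA"), ("HIS", "CB"), ("HIS", "CE1"), ("GLU", "OE1")):
    e = model.entries[key]
    refs = ", ".join(f"{n}@{o}" for n, o in e.ref_spec.refs)
    print(f"{key[0]}/{key[1]:>4}: refs [{refs}]  k={e.centroid_set.k}")
# refs are (atom, residue offset): 0 = same residue, -1 = previous.
# CB is backbone-determined (k=1); slots past CB see both conformers (k=2).
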