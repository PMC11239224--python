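# Prediction-model file format

A model file is canonical JSON (sorted keys, no whitespace):

```json
{
  "magic": "PROSTAR-MODEL",
  "version": 1,
  "entries": {
    "HIS:CE1": {
      "refs": [["CD2", 0], ["CA", 0], ["ND1", 0]],
      "centroids": [[r12, r13, r23, f1, f2, f3], ...]
    }
  }
}
```

* Entry keys are `RESIDUE:ATOM` (3-letter residue code, atom name; `OXT`
  keys cover terminal oxygens).
* `refs` are the three reference atoms as `[atom_name, residue_offset]`
  with offset 0 (current residue) or -1 (previous residue), ordered by
  ascending mean training distance.
* `centroids` are k-means centers in the 6-D distance-tuple space, in Å,
  rounded to at most 6 decimals (the shipped model uses 3).

The model **fingerprint** is the 64-bit BLAKE2b digest of exactly this
canonical serialization, so it is stable under save/load cycles.  Every
structure entry in an archive records the fingerprint of the model it was
encoded with, and extraction verifies it against the loaded model —
archives built with different models can never be mixed.

The packaged default model lives at `src/prostar/data/default_model.json`
and can be regenerated with `prostar.models.train_default_model()`;
user models are produced by `prostar train --corpus DIR --out model.json`.
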