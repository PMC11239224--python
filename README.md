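# prostar

Random-access archiving of protein structure predictions: PDB/mmCIF
structure files, PAE (Predicted Aligned Error) matrices and per-residue
confidence files, compressed far below gzip while any single entry stays
extractable in O(1).

Prediction databases (AlphaFold DB, ESM Atlas) hold hundreds of millions
of structures whose dominant payload is the Cartesian atom coordinate
table.  `prostar` is for people who keep local slices of such databases:
it packs many files into one archive, each compressed independently, with
listing and per-entry extraction that touch only the directory and the
entry's own bytes.

## The core idea

Atom coordinates are coded *predictively*.  For every (residue type, atom
type) slot a trained model stores three **reference atoms** — the
already-decoded atoms closest on average — and k cluster centers
("centroids") of the tetrahedron distance tuples
⟨r₁₂, r₁₃, r₂₃, f₁, f₂, f₃⟩ observed in a training corpus.  To code an
atom, each centroid's apex distances are trilaterated over the *actual*
reference triangle, producing two mirror-image candidate positions; the
encoder keeps the candidate whose residual Δ = (Δx, Δy, Δz) in mÅ is
cheapest under

    cost(Δ) = log₂(1+|Δx|) + log₂(1+|Δy|) + log₂(1+|Δz|),

and entropy-codes the centroid id, the mirror bit and the residual with an
adaptive range coder.  k itself is chosen during training as the argmin of
this cost plus log₂(1+k) bits for the id — compression cost, not geometric
error, drives every choice.

Compression is lossless (byte-exact) by default.  The lossy mode takes a
maximum Euclidean error per atom class (backbone / side chain, in mÅ),
snaps all coordinates to a grid with step r ≈ 2m/√3 chosen so that
√3·⌈r/2⌉ ≤ m, and then codes the snapped values losslessly — the error
bound is a worst-case guarantee.  PAE matrices get an image-style codec:
direction-adaptive neighbor prediction with an 8100-state context model,
plus four lossy levels that quantize the [0, 32] range into 24/16/12/10
groups decoded as ⌊(ℓ+r)/2⌋.

## Worked example

```sh
$ prostar gen-fixtures --out corpus --n 10 --seed 42
wrote 30 files under corpus
$ prostar add demo.psar corpus/* -v
synth_0000.cif: 15990 -> 1033 bytes (x15.48, cif)
synth_0000.confidence.json: 378 -> 242 bytes (x1.56, confidence)
...
$ prostar list demo.psar | head -3
synth_0000.cif	cif	1033 B
synth_0000.confidence.json	confidence	242 B
synth_0000.pae.json	pae	412 B
$ prostar get demo.psar synth_0000.cif -o back.cif && cmp back.cif corpus/synth_0000.cif && echo identical
identical
```

The same from Python (`examples/archive_roundtrip.py`):

```
30 files (186121 B raw) -> archive 17960 B (ratio 10.36x)
byte-exact extractions: 30/30
```

The ratio is raw/compressed over the whole synthetic corpus; every
extracted file compares byte-identical to its input.  Lossy mode
(`examples/lossy_bounds.py`) shows the bound in action — the worst
per-atom error (mÅ) always stays inside the requested budget:

```
bound bb/sc [mÅ]   max err bb    max err sc    stream bytes
   10/10                8.7           8.7            9804
   80/140              74.1         133.4           10073
  200/300             190.1         279.8           10439
```

Other entry points: `prostar add --lossy-bb 80 --lossy-sc 140
--pae-level 2 --minimal ...` for lossy archiving, and
`prostar train --corpus DIR --out model.json` to retrain the coordinate
predictor on your own structures (archives record the model fingerprint,
so mismatched models are refused at extraction, never silently decoded).

See `docs/methods.md` for the model details and `examples/` for short
narrative scripts per capability.

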