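# Methods

`prostar` compresses the three file families that structure-prediction
databases distribute — PDB/mmCIF structure files, PAE (Predicted Aligned
Error) matrices, and per-residue confidence files — into a single archive
with O(1) listing and per-entry random access.  This note describes the
models and procedures, the parameters that matter, and the limits of what
the synthetic test corpus can show.

## 1. File model and the lossless contract

A structure file is split into an ordered list of sections, each a *block*
(header/footer text) or a *table*.  Tables are classified:

* **atom** — one or more chains of the 20 canonical amino acids, atoms in
  the canonical PDB v3 order (N, CA, C, O, side chain in wwPDB
  chemical-component order; OXT allowed as the last atom of a chain's final
  residue), no alternate locations or insertion codes, consecutive serial
  numbers (a PDB TER consumes one), and — decisively — a byte-exact match
  between the parsed records' canonical re-serialization and the input
  text.
* **hetatm** — all rows HETATM with no missing fields (encoded like
  generic tables).
* **generic** — everything else.

"Lossless" here means *byte-exact file reconstruction*: classification
verifies re-serializability up front, and any table that cannot be
reproduced exactly is demoted to generic column coding or, for rows that
do not even tokenize canonically, stored as verbatim Zstandard-compressed
text.  Files that cannot be parsed at all (e.g. undecodable bytes) become
opaque blobs, flagged as such in the archive directory.  Nothing is ever
silently altered.  Two deliberate exceptions: PAE and confidence files are
reduced to their semantic content (the matrix, the three arrays) and
re-serialized in a canonical compact JSON dialect — byte-exactness holds
for files already in that dialect.

Coordinates are fixed-point integers in milli-Ångström (mÅ; PDB and mmCIF
print 3 decimals), occupancies and B-factors in hundredths, which makes
all lossless arithmetic exact and avoids float re-formatting drift.

## 2. Coordinate prediction by clustered tetrahedra

Every atom after a chain's first three is predicted from three *reference*
atoms.  Training, per (residue type, atom type):

1. **Reference choice.**  Candidates are the already-coded atoms of the
   current residue plus the previous residue's backbone (N, CA, C, O).
   The three candidates with the smallest mean distance over the corpus
   are kept, ordered by ascending mean.
2. **Observations.**  Up to `n_max` (default 10^6) distance 6-tuples
   `(r12, r13, r23, f1, f2, f3)` — base-triangle edges and apex distances,
   i.e. a tetrahedron up to rigid motion and reflection.  Degenerate
   tuples (non-positive distances, triangle-inequality violations beyond
   1e-9) are skipped; sampling is first-N in deterministic corpus order.
3. **Clustering.**  k-means (k-means++ init, 4 restarts, 50 iterations,
   seeds derived from the slot identity) for k = 1..20; duplicate
   centroids collapse.
4. **k selection.**  The kept k minimizes the estimated encoding cost of
   the observations: for each observation its base triangle is embedded
   canonically, every centroid predicts the apex by trilateration (both
   mirrors), and the cheapest residual under
   `log2(1+|dx|) + log2(1+|dy|) + log2(1+|dz|)` (mÅ) plus `log2(1+k)` bits
   for the centroid id is charged.  This mimics compression; ties prefer
   smaller k.

At encode time the actual reference positions form the base; each centroid
contributes its two mirror-image trilaterated apexes; the encoder picks
the (centroid, mirror) pair whose residual is cheapest under the same
cost — deliberately *not* the smallest Euclidean error.  The chosen
centroid id, mirror id and residual are entropy-coded.  A *fast* mode
instead picks the single centroid nearest (6-D Euclidean) to the atom's
own tuple and only chooses the mirror by cost; it is never better than the
full search and slightly larger in practice.

Determinism and symmetry: predictions are computed from *reconstructed*
positions on both sides and rounded to integer mÅ (half away from zero)
before residuals are formed, so encoder and decoder agree bit-exactly on
one platform.  Bit-exactness across differing math libraries would require
identically-rounded trilateration; archives record the model fingerprint,
and extraction with any other model is refused.

Fallbacks: a degenerate base (triangle area < 1e-6 Å^2) or unmeetable
spheres make a centroid predict the first (mirror 0) or second (mirror 1)
reference position.  Atoms whose references do not exist — slots of the
first residue whose trained references sit in the previous residue, or a
terminal OXT absent from the model — are delta-coded against the previous
atom; the decoder detects the same condition, so no side information is
needed.  Atoms outside model coverage demote the whole table to generic
handling (never data loss).

## 3. Bounded-error lossy mode

The user bounds the maximum Euclidean error separately for backbone
(N, CA, C, O, OXT) and side-chain atoms.  For a bound m (mÅ) the grid step
is `r = floor(2m/sqrt(3))`, decremented until
`sqrt(3) * ceil(r/2) <= m` holds in integer arithmetic; every coordinate
is snapped to `floor((x + floor(r/2)) / r) * r` per axis *before*
encoding, and the pipeline then runs losslessly on the snapped values.
The per-axis error is at most `ceil(r/2)`, hence the Euclidean error is at
most m — a hard worst-case guarantee, not an average.  The centroid model
is pruned first: centroids whose canonical apex placements round to the
same grid cell merge (first kept), shrinking the id alphabet.  Rounding
the inputs degrades prediction accuracy somewhat; the bound is unaffected.

B-factors are stored one value per residue when they are constant within
each residue (the AlphaFold pLDDT case), else per atom; `bf_average`
forces the per-residue arithmetic mean (rounded half away from zero to 2
decimals) — a lossy choice the user opts into.  *Minimal* mode archives
only the leading block and the atom tables of a structure file.

## 4. Entropy coding

All codecs share a byte-wise renormalizing range coder (32-bit range,
64-bit low with carry propagation) over adaptive frequency models: counts
start at 1, grow by 32 per coded symbol, and halve (rounding up) when the
total reaches 2^16 — fast adaptation suited to short per-file streams.
Signed residuals are binarized as a bucket symbol (zero, or sign plus
magnitude class `floor(log2 |d|)`) followed by raw offset bits, so the
coded cost tracks `log2(1+|d|)` up to a constant; the i.i.d. compression
excess over Shannon entropy comes out at a fraction of a percent in the
acceptance measurements.
Stream layout details are in `docs/bitstream.md`.

## 5. PAE codec

PAE matrices are n×n integers in [0, 32].  Cells are scanned row-major and
predicted horizontally or vertically; the direction is chosen from causal
per-row/per-column counts of which neighbor difference has been strictly
smaller (ties and borders go horizontal).  The prediction itself encodes
PAE structure: 0 on the diagonal, 1 on the first off-diagonals, the left
(resp. upper) neighbor otherwise, nudged by ±1 when the two neighbors
contrast by more than 4.  The prediction error is coded in one of
8100 contexts: two 5-way quantized neighbor differences, three 3-way
ones, the 6-way quantized previous value, and the direction flag.
Missing border neighbors contribute difference 0 / value 0, and cell (0,0)
reduces to a literal.

Lossy levels 1–4 map values onto 24/16/12/10 fixed groups; the identical
machinery runs on group indices with thresholds applied to group
representatives, and decoding yields `floor((lo+hi)/2)` per group.  Level
0 is the 33-singleton case of the same code path.

## 6. Archive container

`PSARv001` magic, sequential independently-compressed payloads, a
Zstandard-compressed JSON directory, and a fixed 32-byte footer holding
the directory's offset, length and checksum.  Listing reads only footer +
directory; extraction reads one payload range and verifies an 8-byte
BLAKE2b checksum; appending truncates the tail directory and rewrites it
after the new payloads, leaving existing bytes untouched, so
append-then-reopen equals single-pass creation.  Archive bytes are a pure
function of (inputs, parameters, model, format version); the CLI accepts
`--threads` for interface compatibility but processes files sequentially —
per-file compression is embarrassingly parallel and order-committed, so
the output contract is thread-count independent either way.

## 7. Synthetic corpus: what it shows and what it does not

The fixture generator builds polypeptide chains with canonical atom
compositions on an idealized α-helical backbone (radius 2.3 Å, rise
1.5 Å, 100° turn), side chains grown from fixed per-(residue, slot)
template directions at 1.5 Å steps with `conformer_count` discrete
rotamer-like variants, Gaussian coordinate noise (default 0.05 Å),
per-residue-constant B-factors, and PDB/mmCIF serializations in the
package's canonical dialects.  PAE fixtures are banded matrices growing
toward 32 with seeded integer noise; confidence fixtures follow the
AlphaFold three-array shape.

Passing tests on this corpus demonstrate the *contracts* — byte-exact
roundtrips, hard lossy bounds, decoder/encoder symmetry, model-selection
consistency — on inputs with realistic local geometry.  They do not
demonstrate real-data compression ratios: synthetic noise levels, residue
usage and PAE textures differ from AlphaFold outputs, and real mmCIF files
use aligned-column formatting that this implementation handles via the
(well-compressing but less specialized) generic path rather than the atom
path.

Two regimes deserve explicit mention:

* **k recovery.**  With any appreciable coordinate noise the encoding-cost
  criterion legitimately selects more centroids than there are conformers —
  splitting the noise ball keeps paying until the `log2(1+k)` id cost
  catches up (consistent with k reaching 20 on real data).  The recovery
  experiments therefore use the separation-much-greater-than-noise limit:
  noise 0 on a translation-symmetric backbone (`FixtureSpec(helical=False)`,
  3.8 Å rise), where integer-mÅ coordinates make each conformer's tuple an
  exact point mass and the criterion returns exactly one centroid per
  conformer.  CB is deliberately conformer-independent in the generator
  (as in real proteins, where rotamers start at χ1), so its recovered k
  is 1.
* **Lossy compression gains.**  On real structures coarser grids shrink
  files substantially; on the synthetic corpus the 0.05 Å noise floor
  dominates the residuals, so lossy streams are not much smaller than
  lossless ones.  The acceptance quantity is the error *bound*, which is
  grid-guaranteed and independent of this.

## 8. Shipped model and problem sizes

The packaged default model is trained on a seeded fixture corpus
(40 structures × 50 residues, all 20 residue types, 2 conformers, 0.05 Å
noise) with k capped at 4 and centroids stored at 1 mÅ precision — a
packaging choice keeping the JSON small and encoding fast; the API and
CLI trainer default to the full k range 1..20.  Test and acceptance runs
use corpora of 100 structures × 25 residues (plus matching PAE and
confidence files), 10^4 random tetrahedra for the trilateration oracle,
and 1000 random streams for coder fidelity; these sizes were chosen so the
full suite completes in well under a minute while every contract is
exercised at its stated scale.

## 9. Known limitations

* Multi-model (NMR) files, nucleic acids, modified residues, alternate
  locations and insertion codes all take the generic path.
* Real AlphaFold mmCIF column alignment is preserved byte-exactly but via
  generic/ragged handling, not the atom predictor.
* Archives are not compatible with other tools' formats; entry deletion
  and compaction are out of scope.
* Cross-platform bit-identical archives require identical floating-point
  trilateration behavior (see §2).
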