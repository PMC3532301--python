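# Methods

## Model

A reaction is represented by the signed, stoichiometry-weighted difference
of counted linear-fragment vectors between its two sides (the *reaction
difference fingerprint*, RFP), and classified by the EC sub-subclass of its
Euclidean-nearest labelled neighbour. The approach assumes that reactions
catalysed by the same enzyme sub-subclass share a bond-pattern change —
which bonds appear and disappear, together with their local connectivity up
to a few bonds — and that this change varies less within a sub-subclass
than between sub-subclasses. Nothing about mechanism, kinetics or
three-dimensional structure enters the model.

## Fragment dialect

The fragment vocabulary is fixed by four choices, recorded in every output
header:

* **Atom symbols** are element symbols, lower-cased on aromatic atoms.
  Formal charges are appended (as `N^+1`) only when `with_charge` is set;
  the default is off, the minimal dialect consistent with the racemase
  zero-fingerprint behaviour. Hydrogens are implicit and never appear in
  fragments.
* **Bond symbols** are `-`, `=`, `#`, `:` for single/double/triple/aromatic.
  Kekulised input is re-aromatised by RDKit's standard perception before
  enumeration, so the dialect is stable across SMILES and molfile input.
* **Paths** are simple paths (no repeated atom) of 0..`max_len` bonds;
  ring-closure and branched fragments are not emitted. A fragment string is
  canonical when it equals the lexicographic minimum of its forward and
  reversed spellings.
* **Counting convention.** With `directed=False` (default) a path and its
  reverse count as one occurrence; with `directed=True` both orientations
  count, doubling every length-≥1 coordinate and hence doubling distances
  between balanced reactions (whose length-0 terms vanish either way).
  The original implementation delegated fragment counting to an external
  package without stating its convention; its published worked minimum
  distance of 2 between the tryptophan- and serotonin-methylation
  fingerprints is reproduced exactly by directed counting (the difference
  is a single coordinate, `C-C-N-C`, at ∓2) and halves to 1 under
  deduplicated counting. Classification is invariant to the choice — it
  rescales all distances between balanced reactions by the same factor —
  but reported distances are not, so the convention is part of the dialect
  and incomparable fingerprints raise an error. Package defaults use
  deduplicated counting; the worked-example distance and the acceptance
  script use `directed=True`, the convention on which the original
  distances live.

Stereochemistry is discarded on parsing. This is a feature, not a loss:
racemases and epimerases then have exactly zero difference fingerprints,
which is the behaviour the dataset filter (category 6) relies on.

## Distance and tie-breaking

Distances are compared on exact integer squared values; the square root is
taken only for reporting, so there is no floating-point ambiguity in which
training reactions attain the minimum. Among minimum-distance supporters
the most frequent 3-level EC wins (supporters are counted per training
*reaction*, not per distinct EC); residual frequency ties break on the
lexicographically smallest EC. The tie-break makes assignment a pure
function of the training *set*, independent of its order — a requirement
for reproducible cross-validation. The distance is the Euclidean norm, not
its square: under directed counting the norm reproduces the published
worked minimum of 2 exactly (the squared distance would give 4).

EC labels deeper than the sub-subclass are truncated on ingest; labels
shallower than three defined components are rejected rather than padded.

## The exclusion filter

The six cases are tested in a fixed declared order (1 unbalanced, 2 glycan,
3 no EC, 4 no structure, 5 wildcard atoms / symbolic coefficients, 6 zero
RFP) and the first match is recorded; the original description notes the
cases overlap without fixing an order, so the order is declared in every
report header. Two proxies deserve mention:

* **Balance (category 1)** is tested as equality of coefficient-weighted
  heavy-atom element counts — implicit hydrogens cannot be compared on
  H-suppressed structures. The test is skipped (never fires) when any
  participating structure is unknown, wildcard-containing, or has a
  symbolic coefficient; such reactions fall through to categories 4/5.
* **Glycans (category 2)** are detected by the `G` id-namespace prefix,
  with an override list for false positives, since glycan entries are not
  atom-resolved structures.

An id absent from the compound table altogether is a data-integrity error,
deliberately distinct from category 4 (a compound *declared* structureless).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_len` | 3 bonds | fragment path length; 3 is the value validated by the original length sweep, and the synthetic sweep below shows the qualitative optimum shape |
| `directed` | False | path-counting convention (see above) |
| `with_charge` | False | formal charges in atom symbols |
| bin edges | 0,10,20,30,40,50 | distance-histogram edges; multiples of 10 with the 20 and 50 cut-offs the distance interpretation emphasises, last bin open above |

## Synthetic study conditions

The generator combines hand-curated scaffolds (≤ 12 heavy atoms, so every
fingerprint is hand-enumerable) with transformation templates standing in
for enzyme sub-subclasses. Each template carries a SMARTS site pattern, an
RDKit graph edit, an optional cosubstrate/coproduct pair that balances the
equation, and a 3-level EC label. Defaults: secondary-alcohol oxidation
(1.1.1, formaldehyde as hydride acceptor), amine N-methylation (2.1.1,
methanol donor), alcohol amination (2.6.1), alcohol phosphotransfer (2.7.1,
pyrophosphate-type methyl-diphosphate donor), ester hydrolysis (3.1.1),
amino-acid decarboxylation (4.1.1), five reactions per template, seeded
sampling of (scaffold, site) combinations without replacement and no global
random state. A racemisation template (5.1.1) is emitted only on request,
to exercise filter category 6.

The class geometry is designed, not accidental:

* methylation and amination share their *entire* length-1 fingerprint
  (`{C-O:+1, C-N:−1}`) and separate at length ≥ 2, giving the length sweep
  a discriminating path length of 2: sub-subclass accuracy is 1/3 at
  length 1 and 1.0 at lengths 2–3, for every seed;
* oxidation, hydrolysis and phosphotransfer conserve the length-1 bond
  inventory (zero RFP at length ≤ 1) and are excluded there by the
  re-applied category-6 filter, mirroring how short fragments lose
  information on real corpora;
* each template's site pattern confines it to a homologous substrate
  series, keeping within-class spread (squared distance ≤ 2 between
  nearest same-class members for the overlapping pair) below the smallest
  between-class gap (squared distance 4, methylation vs amination), which
  is what makes leave-one-out recovery exactly 1.0 at length 3 for every
  seed;
* the `DISJOINT_TEMPLATES` subset (methylation, phosphotransfer,
  hydrolysis, decarboxylation) has pairwise non-overlapping edit-signature
  coordinates at length 3, and on sets generated from it every
  between-class distance strictly exceeds every within-class one — the
  stronger separation property asserted exhaustively in the tests. The
  full default set intentionally violates it (methylation/amination are
  near neighbours by design), which is the realistic regime where the
  majority rule matters.

What the generator does **not** emulate: cofactor promiscuity, multiple
simultaneous bond changes, unbalanced or generic (R-group) equations as
they occur in real KEGG data, EC classes 5 and 6 among the default
templates, and the long-tailed distance distribution of a 5000-reaction
corpus. A perfect synthetic cross-validation score therefore demonstrates
correctness of the pipeline and the designed geometry, not the accuracy to
expect on curated corpora — those require the licence-restricted KEGG set
and are outside this package's reproduction scope.

## Numerical and degenerate-input choices

* All fingerprint arithmetic is exact integer arithmetic; the only floats
  are reported distances and accuracies.
* Zero-RFP queries and training members are refused with a pointer at the
  filter rather than silently scored: a zero vector is equidistant from
  everything and its assignment would be the tie-break's artefact.
* A length sweep keeps rows whose filtered set has < 2 members and reports
  NaN accuracies (at length 0 every balanced reaction has a zero RFP, so
  the kept set is empty by construction).
* Equation terms split on `+` only at parenthesis depth zero, so polymer
  coefficients like `(n+1)` survive to be classified as filter category 5;
  strict parsing contexts reject them with a position-annotated error.
* Empty molecules yield empty fingerprints; single-heavy-atom molecules
  yield exactly one length-0 fragment at every `max_len`.

## Problem sizes

The test suite and acceptance script run on the worked-example reactions
(≤ 27 heavy atoms per molecule) and synthetic corpora of 30–35 reactions
over ~57 compounds; the brute-force enumeration oracle covers 200 random
graphs of ≤ 10 heavy atoms. Everything completes in seconds on one CPU.

## Known limitations

* Linear fragments cannot see stereochemistry (racemases are unclassifiable
  by construction) or distinguish intra- from inter-molecular versions of
  the same bond change; both failure modes are inherited from the method.
* The balance proxy ignores hydrogens, so proton-only imbalance passes
  category 1.
* Symbolic stoichiometry is excluded, not expanded.
* 4-level EC prediction and probabilistic confidence are out of scope; the
  classifier returns the sub-subclass of the nearest neighbour and the
  supporting evidence (distance, supporter ids, tie flag) for the caller to
  judge.
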