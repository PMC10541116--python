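# Methods

## The distance model

A cleavable amine-reactive cross-linker of DSSO's geometry couples lysine
side chains whose Cα atoms lie within ~30 Å (linker spacer plus two side
chains). We treat this as a hard classification boundary on the Euclidean
Cα–Cα distance d of a link mapped onto an atomic model:

- **satisfied**: d ≤ 30 Å (boundary inclusive),
- **moderate**: 30 < d ≤ 40 Å — compatible with modest conformational
  spread or coordinate error,
- **extreme**: d > 100 Å — geometrically impossible within one copy of
  the complex,
- **violated**: everything between 40 and 100 Å.

Distances are Cα–Cα Euclidean, not solvent-accessible surface paths;
SASD is deliberately out of scope. Thresholds are parameters
(`Thresholds(satisfied, moderate, extreme)` in Å) validated to satisfy
`satisfied ≤ moderate < extreme`.

## Records, filtering, unique links

One table row is one cross-link spectral match. The identification
filters default to FDR ≤ 0.01 (inclusive) and score > 40 (strict), the
conventional operating point of cleavable-linker workflows; both are
parameters. When an exported table carries no FDR column the records pass
the FDR filter by default with a warning, since public tables are often
deposited pre-filtered.

Unique links are canonical unordered residue pairs: endpoints are sorted
lexicographically by (group id, residue), so permuting the input or
swapping endpoints can never change any downstream output. Support is
the number of contributing records; the best score is their maximum. A
link is intermolecular iff its two groups differ *after* orthogroup
collapsing — two cross-linked paralogs of one family count as an
intramolecular link at the family level, which is the granularity the
interaction network is reported at. Both unique residue pairs and unique
group pairs are reported, since the two counts answer different
questions (depth vs breadth) and are not interconvertible.

## Orthogroup collapsing and residue transfer

Accession → orthogroup tables (eggNOG-style, one group per accession,
ambiguity is a hard error) relabel records to family level; unmapped
accessions become singleton groups under their own name and are tallied,
never dropped. Original accessions are retained in each record's
provenance.

Cross-species placement of residues uses global Needleman–Wunsch
alignment with affine gaps (Gotoh recursion), BLOSUM62, gap open 11 and
extend 1 (a gap of length L scores −(11 + (L−1)·1), the same convention
as Biopython's `PairwiseAligner`), with `X` scored 0 against everything.
Traceback tie-breaks are fixed — diagonal, then up, then left — so the
alignment, not just its score, is deterministic. Transfers are refused
wholesale when global identity (identical pairs over alignment columns)
falls below 20%, a guard against spurious mapping between unrelated
sequences. Both transfer paths are supported: alignment-based
(`build_transfer`) for structures of a homolog species, and direct
author-numbering (`identity_transfer`) when the structure already carries
the cross-linked species' numbering. Author numbers are assumed to equal
target-sequence positions up to a constant offset; by default the offset
anchors the chain's first residue at sequence position 1, and it is
overridable for structures with arbitrary numbering.

## Mapping and ambiguity rules

Every unique link yields exactly one mapped record: either a numeric
distance with a category, or an explicit unmappable reason
(`protein_absent`, `unaligned`, `missing_in_structure`). Fractions are
computed over numeric distances only; unmappable links are tallied
separately, mirroring how satisfaction statistics are conventionally
quoted "of N mapped links". When a group occupies several chains
(homo-oligomer) the chain pairing with minimal distance is chosen and
recorded — the only self-consistent convention when copies are
indistinguishable, and the same logic the lattice step generalizes.

For ensembles, the per-link minimum over conformations decides
satisfiability ("satisfied by at least one state"); unmappable cells are
ignored by the minimum rather than treated as infinite violations, with
a flag when a link is unmappable everywhere. For head-to-tail lattices
(copy k = Tᵏ(base), T a proper rigid transform supplied by
configuration — no axonemal 96 nm repeat is assumed), a violating link
(i, j) is re-evaluated as min over ordered copy pairs k ≠ l of
d(copyₖ·i, copyₗ·j); the search is exhaustive over pairs, which is cheap
at the default 3 copies and avoids adjacency assumptions.

## Superposition and fitting

Kabsch superposition is computed by SVD of the cross-covariance with the
reflection corrected through the sign of the smallest singular value, so
the returned rotation is always proper (det = +1) — a mirrored point set
is *not* matched. Degenerate inputs (n < 3 or collinear) are hard errors.
Correspondence for model-to-backbone fitting uses Cα atoms over residues
resolved in both, either by author number (`sequence-aligned`) or by
sliding the model trace along the target's resolved Cαs and fitting at
every offset (`sliding-window`; ties break to the smallest offset). The
full offset-vs-RMSD profile is returned so a fit's uniqueness can be
inspected, and a placed model's cross-links are re-checked with the
standard distance rules.

## Structure and table IO

PDB/mmCIF reading goes through gemmi (first model only). Alternate
locations keep the Cα with highest occupancy, ties broken alphabetically
by altloc. Insertion codes are part of the author numbering sort key
(number, icode). Residues without a Cα are kept with an explicit missing
marker, never a sentinel coordinate; chains with zero Cαs warn but are
retained. Cross-link tables are parsed through a configurable column
dialect (the export schemas of identification software vary); every row
becomes exactly one record or one warning-logged skip, and self-links
are rejected at parse time.

## The synthetic study system

The generator emulates the four inputs the pipeline consumes, with known
truth:

- **Chains**: Cα traces with 3.8 Å steps — either self-avoiding random
  walks (uniform random directions, ≥ 3.0 Å clearance to non-adjacent
  predecessors) or ideal helices (2.3 Å radius, 1.5 Å rise, 100°/residue).
  Defaults: 5 proteins of 80–140 residues, each chain seeded ~10 Å from a
  random residue of the previous one so inter-chain contacts exist.
- **Cross-links**: true links uniform over residue pairs with true
  distance ≤ 25 Å (the bulk of the linker's reach, leaving headroom to
  the 30 Å classification bound), sequence separation ≥ 3; false links
  uniform over all eligible pairs at a 10% default rate; duplicates
  (possibly endpoint-swapped) injected at 15%. True links score
  N(90, 20) with FDR ≤ 0.009, false links N(35, 15) with FDR ≤ 0.05 —
  a confident true population against a low-scoring false one, so the
  default filters remove most false links before classification.
- **Ensembles**: a rigid hinge — residues past a pivot rotated about an
  axis through the pivot Cα; planted state-specific links are ≤ 25 Å in
  their generating state and > 40 Å in the other.
- **Lattices**: an extended helix spanning > 100 Å, translated
  head-to-tail with an 8 Å gap; planted links join head to tail
  (intramolecular distance > 100 Å, inter-copy distance ≤ 25 Å by
  construction), negatives are endpoint-shuffled pairs.

All randomness flows from one seed through named per-task generators, so
adding a generator never perturbs existing streams.

What the synthetic system does *not* emulate: real protein topology and
packing, lysine-specific reactivity (links are sampled over all residue
pairs), distance-dependent cross-linking efficiency, peptide-level
identification ambiguity, and coordinate error in experimental models.
Passing tests therefore demonstrate the correctness of the bookkeeping,
geometry and decision rules — not that any particular experimental
dataset will show particular satisfaction rates.

## Validation quantities and problem sizes

`scripts/acceptance.py` reruns the entire synthetic study at the default
sizes (5 proteins, ~150 records, ~10–20 planted links per
ensemble/lattice case, 20-residue fit windows on 60-residue chains) —
small enough to complete in seconds while leaving every decision rule
exercised — and reports recovery rates, reinterpretation rates and fit
errors. The alignment optimality check in the test suite is exhaustive:
all 115,600 ordered sequence pairs of length ≤ 4 over a 4-letter
alphabet against brute-force path enumeration.

Validation against the deposited experimental data (the published
cross-link tables and PDB entries 7K58/7K5B/7KEK/7JTK) is encoded as a
regression test that requires those downloads under `data/deposited/`;
it documents the expected published counts and runs the identical
pipeline stages once the files are present.

## Known limitations

- Euclidean Cα distances overestimate satisfiability for links whose
  straight-line path crosses the protein core (no SASD).
- The residue-transfer offset heuristic assumes consistent author
  numbering; structures with renumbered or segmented chains need an
  explicit offset.
- The lattice search is exhaustive over copy pairs, which is quadratic
  in copy count — fine at 3–10 copies, not meant for large assemblies.
- Alignment is pairwise only; no profile or HMM information is used, so
  the 20% identity gate is deliberately conservative.
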