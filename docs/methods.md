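# Methods

This note records the model, the numerical choices and the limits of the
bundled data, in the package's own terms. Nothing here states a number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Charge blueprints

A molecule enters the aligner as its canonical SMILES (RDKit writer; the
backend is pluggable behind `canonicalize(smiles, backend=...)`, whose
contract is determinism and idempotence). The string is split into *atom
tokens* and a *skeleton*:

- two-letter organic-subset halogens (`Cl`, `Br`) are single tokens;
- aromatic lowercase atoms (`c`, `o`, `n`, `s`, `p`, `b`) are tokens,
  normalized to their element symbol;
- a bracket atom `[...]` is one token whose span covers the whole bracket —
  isotope labels, charges and H-counts travel with the atom, not the
  skeleton;
- implicit hydrogens are never tokens (charge providers report heavy-atom
  charges); explicit `[H]` would be a token;
- everything else (bond symbols, ring-closure digits and `%nn`, parentheses,
  dots) stays in the skeleton, one NUL placeholder per atom marking where a
  token was removed.

Gasteiger-Marsili PEOE charges are attached per token via RDKit
(`AllChem.ComputeGasteigerCharges`); the provider is a plain callable
`Mol -> [charge]`, so other charge models can be dropped in. Non-finite
charges (NaN/±inf, produced by unusual atom types or numerical trouble in
the iterative charge model) cause the atom to be removed from tokens,
charges *and* skeleton, with one warning per atom naming the molecule;
silent removal would corrupt alignments invisibly. A molecule whose atoms
are all removed is an error. The empty SMILES is accepted as the empty
blueprint because the alignment contract supports all-gap alignments.

Reinsertion walks the gapped token sequence, emitting skeleton characters
before each real token and the gap symbol (default `-`, configurable) for
gap columns. Because `-` is also a SMILES bond character the reinserted
output is a display string, not guaranteed-parsable SMILES.

## Scoring matrices

All absolute charge differences of a corpus are binned with width 0.1 over
[0, 3): 30 bins, differences ≥ 3 clamped into the last bin. Bin assignment
adds 10⁻⁹ before flooring so decimal edges that are not exactly
representable in binary (0.3/0.1 = 2.999…) land in the intended bin. Raw
scores are survival log-odds, `raw(k) = log₂(#{d ≥ 0.1k}/N)`; the axis
convention is "probability of this difference *or greater*", so `raw(0) = 0`
and the sequence is monotone non-increasing by construction.

Three choices were genuinely open and are isolated in one function each:

- **Empty tails.** When no difference reaches a bin's edge, log₂ 0 is
  undefined; the bin receives a pseudo-count of one observation,
  `log₂(1/N)`. This produces the flat maximum-penalty plateau for extreme
  differences; the plateau level (the matrix *floor*) depends on N and is
  deliberately not a constant.
- **Mean-threshold normalization.** The aligner needs sub-average
  differences rewarded and super-average ones penalized. The minimal
  transform with that sign behaviour is a shift: `score(k) = raw(k) −
  raw(bin(μ))`, μ the mean difference. The bin holding μ scores exactly 0,
  shape is preserved. Alternate normalizations can be swapped in by
  replacing this one subtraction.
- **Paired pooling scope.** Paired matrices (one per unordered element pair)
  pool *cross-molecule* by default: all corpus charges of element A against
  all of element B (same-element pairs use unordered within-list
  differences), mirroring the all-vs-all construction. An
  `intra_molecule_only` flag restricts pooling to within-molecule pairs.
  Pairs with fewer than `min_pair_observations` differences (default 100 —
  survival estimates from tiny samples are degenerate) resolve to the
  all-vs-all fallback, so lookup is total.

Matrices serialize as CSV (bin edge, raw score, normalized score) plus a
JSON sidecar (μ, N, floor, corpus hash) for reproducibility of sweeps.

## Alignment

Full three-state Gotoh recurrence, maximizing. The X↔Y cross transitions
are included: a gap run in one sequence may start immediately after a gap
run in the other, each run paying its own `g_open`. The common two-term
abbreviation (X fed only by M and X) silently forbids that alignment class;
it coincides with the full recurrence only when gaps always cost, and this
package deliberately sweeps negative penalties (gap rewards), where the
abbreviation is strictly suboptimal. Correctness is defined against
exhaustive enumeration of all affine-gap global alignments, and the test
suite checks exact agreement on all instances with lengths ≤ 6.

Numerical conventions:

- penalties are *subtracted*; negative values act as rewards and are passed
  through unchanged;
- boundary: `M(0,0)=0`, M elsewhere on row/column 0 impossible;
  `X(i,0) = −g_open − (i−1)·g_extend`, symmetric for Y;
- impossible states carry a finite sentinel of −10¹², far below any
  reachable score, so lattice arithmetic stays total;
- ties break deterministically with preference M > X > Y (and open-from-M >
  extend > open-across within a gap lattice), so repeated runs emit
  byte-identical alignments;
- traceback follows pointers recorded during the fill, never re-derived
  from float comparisons.

Aligning against the empty blueprint is legal and yields an all-gap
alignment with the closed-form score `−g_open − (k−1)·g_extend`.

## Validation

The two similarity notions are deliberately simple and live behind single
functions: Levenshtein similarity `1 − d/max(|s1|,|s2|)` (edit distance via
edlib; both-empty defined as 1) and exact similarity, the fraction of
identical positions (length mismatch padded with the gap symbol, logged).
Similarities are computed on the gapped *token* strings, not reinserted
SMILES — the stripped representation is what the aligner actually chose.
Per pair, the two molecules' string similarities are averaged; the sweep
grid is integer-stepped, 11 × 11 = 121 cells, ordered g_open-major. Best
parameters are the argmax of mean Levenshtein similarity, ties broken by
smaller Levenshtein−exact difference, then lexicographically.

The bundled truth sets for the Krebs cycle and glycolysis are
**reconstructions, not curated data**: for each molecule pair the RDKit
maximum-common-substructure atom map is projected onto the canonical token
orders, its largest monotone subset (longest increasing subsequence) forms
the aligned columns, and the remainder is gapped. The TSV fixtures carry a
provenance header saying exactly that, and `validation.truth_from_mcs`
regenerates them. A truth set built from shared substructure is a
structural, not biochemical, notion of site correspondence; conclusions
about specific enzymatic atom tracking need manually curated truth.

## Pathways

A pathway is an ordered molecule list, cyclic or linear. Distance between
positions is `min(|i−j|, n−|i−j|)` (cyclic) or `|i−j|` (linear); each
unordered pair is scored once, self-pairs only at distance 0, so a cyclic
profile has ⌊n/2⌋+1 entries whose distance-0 mean is the self-alignment
score — in all-vs-all mode exactly `n_atoms × score(0)` per molecule.
Reported spread is the population (÷N) standard deviation, matching
single-sample summary captions. Linear pathways additionally support a
versus-first mode (each molecule against the starting one), used for the
glycolysis-from-glucose profile and the Tanimoto baseline. Cyclic profiles
are rotation- and reversal-invariant by construction, and the tests assert
it. Tanimoto values use RDKit's hashed path fingerprint (2048 bits, max
path 7), recorded in `validation.FINGERPRINT_PARAMS`; the coefficient is a
baseline, not part of the aligner.

## Bundled data and the random generator

The fixture corpora are reconstructed textbook structures: the seven
primary Krebs metabolites (coenzymes and CoA-bound intermediates excluded),
ten glycolysis main-chain metabolites glucose→pyruvate, and an
eight-member pentose-phosphate cycle, plus a twelve-molecule mixed demo
set. Sugars are written open-chain for a uniform backbone representation;
acids and phosphates are neutral. These choices fix the study conditions
for every desk-scale test; the combined pool (35 unique molecules, ~59k
charge differences) is the default matrix corpus. What the bundled data
does *not* emulate: corpus scale (a metabolome-wide reference corpus has
three orders of magnitude more differences and a correspondingly deeper
floor), charged/tautomeric species, stereochemistry, and ring-form sugars.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative cyclic/linear signatures, not the numeric profiles of any
full-scale corpus.

`fixtures.random_smiles` builds seeded random molecular graphs over
{C, O, N, S} with valence bookkeeping (C 4, N 3, O 2, S 2), 20%
double-bond probability where capacity allows, at most one ring, and emits
canonical SMILES — validity is guaranteed by construction rather than by
filtering a string grammar. Charged atoms (an N⁺) appear only behind an
explicit flag so default charge computation stays well-behaved.

## Problem sizes

The test suite and acceptance script use: 200 random alignment instances
with lengths ≤ 6 under 20 penalty settings each against the brute-force
enumerator; 60 toy pools of ≤ 10 values for the survival recount; 50 random
corpora for the normalization contract; the 35-molecule combined corpus for
matrices; 500 generated molecules (plus all bundled ones) for round-trip
checks; and the full 121-cell sweep over the 21 Krebs pairs. These sizes
make the whole suite run in seconds while covering every code path.

## Known limitations

- Alignment quality inherits canonicalization stability: the S-for-O
  experiment (`canonization_stability`) shows single-atom edits can reorder
  an entire canonical string, and users should run it on their own data.
- Charge blueprints ignore bond topology beyond its influence on charges;
  two different molecules with similar charge sequences align well.
- The paired matrices key on element pairs only, not hybridization or
  environment.
- Gap rewards (negative penalties) are supported because the validation
  sweep spans them, but alignments produced there maximize gap count and
  are rarely chemically meaningful.
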