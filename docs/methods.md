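# Methods

## Model and assumptions

`codoncomp` models the composition of protein-coding sequences with two
parameters: GC content S = G + C and purine content R = A + G, both
measured on the coding strand over sense codons. Treating S and R as
statistically independent — motivated by Chargaff parity, under which R
stays near 50% while S varies broadly across species — each nucleotide
frequency is a product: A = (1−S)R, T = (1−S)(1−R), G = SR, C = S(1−R).
These four identities conserve probability exactly (they sum to 1 for any
S, R) and reconstruct their inputs (G + C = S, A + G = R). When R = 0.5
they collapse to A = T = (1−S)/2 and G = C = S/2, the single-parameter
GC-content model.

Mutation and selection act differently at the three codon positions, so the
same identities are applied with position-specific contents (S_i, R_i),
i = 1, 2, 3. A sense codon xyz is assigned the product of its positional
nucleotide frequencies x1·y2·z3, renormalised over the 61 sense codons of
the standard genetic code (equivalently, divided by 1 minus the summed
stop-codon products). An amino acid's expected frequency is the sum over
its synonymous codons. Only NCBI translation table 1 is supported; species
with alternative codes are out of scope by construction, and requesting
another table is an error rather than a fallback.

Model 1 and Model 2 differ only in the source of (S_i, R_i). Model 2 counts
them from the input table. Model 1 predicts them from global S and R
through six straight lines (S → S_i and R → R_i), fitted by unweighted
ordinary least squares across a species collection, one point per species.
Cross-predictor independence is preserved: S_i is never regressed on R nor
vice versa. Because a line fitted on mid-range contents can extrapolate
outside [0, 1] at extreme S, Model 1 predictions are clamped into the unit
interval with a logged warning before use.

Model variants built on the complementary contents ({AT, AG}, {GC, TC},
{AT, TC}) are algebraically the same model under the substitutions
S ↔ 1−S, R ↔ 1−R; the equivalence is asserted in a test rather than coded
as separate paths.

## Observed quantities and filtering

All observed quantities — S, R, S_i, R_i, nucleotide frequencies per scope,
codon and amino-acid frequencies — exclude stop codons from numerator and
denominator (an `include_stops` diagnostic flag exists for the content
functions, default off). The unit of analysis is one codon-count table; the
CLI aggregates FASTA records into one table per file by default. Collection
filtering drops tables tabulated from fewer than 64 coding sequences
(inclusive boundary: exactly 64 is kept), requiring `n_cds` metadata.

A structural identity worth noting: global content is exactly the mean of
the three positional contents, S = (S₁+S₂+S₃)/3. Consequently only
relation sets whose slopes average 1 and whose intercepts sum to 0 per
predictor describe realisable collections, and only such sets can be
recovered by regression against observed global contents. The simulator's
`example_relations()` respects this constraint.

## Empirical-relation files

Model 1's prior knowledge is an explicit, versionable artifact: a plain
text key-value file holding provenance, the number of species fitted, and
slope/intercept/r² for each of the six relations, serialised with `repr`
floats so a round trip is bit-exact. No coefficients are shipped as
constants; relation sets are fitted from the user's own collections (the
documented workflow fits them per domain of life or per any collection
scoping the user chooses).

## Simulator design

The simulator generates codon tables with *specified* positional contents,
which is what makes parameter-recovery and round-trip tests meaningful.
Drawing codon positions independently from the (S_i, R_i)-implied
nucleotide frequencies and rejecting stop codons would yield stop-free
tables, but the rejection shifts the sense-codon positional marginals away
from the requested contents by roughly the stop mass (≈0.03 at mid-GC
contents, concentrated on T at position 1 and purines at positions 2–3).
Instead, codons are drawn multinomially from the position-product measure
restricted to the sense support and corrected by iterative proportional
fitting (IPF, converged to 1e-13) so the positional marginals equal the
requested contents exactly. Simulated tables are valid stop-free CDS
bodies; their observed S_i and R_i converge to the specification with
plain binomial error, and Model 2 applied to a large simulated table
reproduces the generating expected codon distribution (total variation
≈ 1e-3 at 10⁶ codons, sampling error only). Contents that force stop
codons (e.g. guaranteed T at position 1 with guaranteed purines at
positions 2 and 3) are an explicit error.

`expected_count_table` exposes the same IPF joint as a deterministic table
with real-valued counts (n_codons × probability), used for noise-free
recovery tests; file readers still enforce integer counts on disk formats.

Default contents, chosen once as a realistic mid-GC bacterial-like
collection: S = (0.55, 0.42, 0.55), R = (0.58, 0.47, 0.50) — GC enriched at
positions 1 and 3 relative to position 2, purine excess at position 1.
Collections space global S evenly over [0.2, 0.8] by default (real
coding-sequence GC spans roughly 17–75%) and global R over [0.40, 0.60],
the "within about 10% of 50%" band purine content occupies in real
collections; R must vary for the R-relations to be fittable at all.
Per-species content noise is Gaussian on the content scale, clamped to
[0.01, 0.99] to avoid degenerate fits. Problem sizes used by the test
suite — 10 species noise-free, 200 species at noise sd 0.01, 10⁶ codons
for round trips — keep every check well-resolved at interactive runtimes.

What the simulator does *not* emulate: phylogenetic correlation between
species, dinucleotide dependence within sequences, indels, and isochore
heterogeneity within genomes. Passing tests therefore demonstrate internal
consistency of the estimators and models, not that real genomes obey the
independence assumptions; on real data the deviations of observed from
expected composition are the scientifically interesting signal, not noise.

## Exchange matrices

The exchange module consumes already-aligned orthologous protein FASTA
(ortholog inference and alignment are upstream concerns). Identity is the
fraction of identical residues over columns where both members of a pair
carry a standard residue (gaps and 'X' excluded from the denominator);
multi-sequence alignments score the mean over unordered pairs. Alignments
with identity below the threshold are removed; the default 0.85 boundary is
inclusive-keep. Counting is the simplest scheme consistent with ranking
exchangeability: every comparable column of every sequence pair increments
the symmetric off-diagonal cell for differing residues or the diagonal for
conserved ones, with no evolutionary-distance correction and no
normalisation by amino-acid frequency (a per-comparable-column rate is
offered as a report column, not as the ranking key). Ranking ties break
lexicographically by pair label so output is deterministic.

## Numerical choices

* Canonical codon order is lexicographic over A<C<G<T; external column
  orders (SPSUM dialect) are mapped onto it at read time via an explicit
  order spec.
* Distribution invariants are validated at 1e-9 in constructors (guarding
  against genuinely broken inputs) and asserted at 1e-12 in tests.
* The codon-expectation normaliser errors below 1e-9 (all probability mass
  on stops).
* OLS fitting requires ≥3 tables and nonzero predictor variance; both are
  explicit errors.
* Report floats are written with 12 significant digits so re-parsed reports
  preserve invariant checks to 1e-9.

## Known limitations

* The codon expectation inherits the positional-independence assumption;
  systematic dinucleotide bias in real genomes shows up as deviation, by
  design.
* Statistical quantification of deviations (distances, divergences,
  significance) is out of scope; the deviation report gives signed
  differences and ratios only.
* Only the standard genetic code is supported.
* The exchange module does not correct for phylogenetic non-independence
  among the sequence pairs of a multi-species alignment.
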