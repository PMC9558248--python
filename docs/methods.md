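# Methods

## Model

The predictor is a linear SVM over hexapeptides reduced to its decision
surface: a 20×6 amyloid effect matrix `M` (per-residue, per-position score
contributions) and a scalar bias `b = 1.083`. The score of hexapeptide
`p = p₁…p₆` is `Σⱼ M[pⱼ, j] + b`; the predicted label is *amyloid* iff the
score is strictly positive. A score of exactly zero is classified
nonamyloid, reading the decision rule literally ("positive ⇒ amyloid,
otherwise nonamyloid"); this makes amyloid the strict class and matters in
practice only inside the rounding band discussed below. SVM training,
feature construction and accuracy estimation are outside this package's
scope — the matrix is taken as published.

## Exact integer arithmetic

The published matrix has two decimals per entry and three on the bias, so
everything is represented in integer *milliunits* (×1000). All scores,
bounds and thresholds are exact integers; there is no floating-point
comparison anywhere near the decision boundary. This matters because the
dataset produces deciding values of exactly ±0.003 and ±0.007. Custom
matrix files are restricted to at most three decimal places and rejected —
never rounded — beyond that, to preserve the guarantee. Serialized scores
are fixed 3-decimal strings.

Raw-position sums on this matrix are multiples of 10 milliunits, so scores
are ≡ 3 (mod 10): the closest achievable values to zero are −7 and +3.

## Patterns and uniform-class certificates

A pattern fixes `k` of the 6 positions (`k` = the *core*) and substitutes
the rest independently from a wildcard alphabet. Because the score is
additive, the minimum (maximum) score over the whole expansion space is the
fixed-slot sum plus the per-column minimum (maximum) over the alphabet at
each free position, plus `b` — a tight bound whose witness is the
per-column argmin/argmax substitution. A pattern is certified
`uniform_amyloid` iff its minimum score > 0 and `uniform_nonamyloid` iff its
maximum ≤ 0 (mirroring the zero-score convention). Fixed slots may hold any
of the 20 residues even under a restricted wildcard alphabet (the published
restricted-class tables do exactly this, e.g. `GxIVxx` with hydrophobic
wildcards).

Uniformity is monotone under specialization (fixing a free slot shrinks the
expansion space, so bounds only tighten) and under alphabet shrinkage.
Consequently a uniform pattern is *minimal* iff every **single**-slot
relaxation loses uniformity — subset relaxations need not be enumerated —
and the freed slot ranges over the pattern's own wildcard alphabet (the
published per-class tables all share one substitution class, which this
convention matches; whether the original analysis freed slots over the
restricted or the full alphabet is not stated).

## Mining

For each requested core size `k`, the miner enumerates all `C(6,k)`
position subsets × `20ᵏ` residue assignments (fixed slots always range over
all 20 residues) and applies the O(1) certificate; with `k` = 1..6 that is
`21⁶ − 1 = 85 766 120` candidates. The scan is vectorized per position
subset — the fixed-slot sum over all assignments is a broadcast cartesian
sum, validity is a threshold test, and the `k` single-slot relaxation tests
for minimality are gather-subtract-compare passes — so the complete
unrestricted sweep finishes in roughly ten seconds on one CPU (the core-4
sweep alone, 2.4 M candidates, well under a second). An optional
`fixed_residues` pool restricts fixed slots for reduced sweeps and oracle
comparisons. Output ordering is canonical and deterministic: position
subsets in lexicographic order, then residue assignments in matrix row
order, position by position; mining TSVs embed the matrix SHA-256 and the
sweep parameters so two runs are byte-identical.

Core 0 (the all-wildcard pattern) is accepted as a candidate and reported
for completeness, although sweeps conventionally start at core 1.

## The rounding band and the boundary flag

The published matrix is rounded from full-precision SVM weights; six
entries plus the bias can shift a sum by up to ~31 milliunits in the worst
case, and the deviations actually observed on the published tables are all
±3 or ±7 milliunits. Every classification therefore carries a
`boundary_flag`, set when the deciding extreme (the min for an amyloid
certificate, the max for a nonamyloid one, either for a mixed verdict) lies
within 10 milliunits of zero. The flag is an audit band, configurable, and
deliberately conservative relative to the observed ±7.

This package defines truth as exact arithmetic on the published matrix and
flags the ambiguity rather than guessing at unpublished precision. The
consequences are measurable and reproducible (`mine` on the default
matrix):

| set | published | exact-arithmetic | flagged in set |
|---|---|---|---|
| nonamyloid, core 2, all | 24 | 24 | 2 |
| amyloid, core 4, all | 5531 | 5615 | 510 |
| amyloid, core 3, small nonpolar | 411 | 432 | 48 |
| amyloid, core 3, hydrophobic | 43 | 46 | 7 |
| amyloid, core 3, polar | 4 | 5 | 2 |
| amyloid, core 1, hydrophobic−P | 38 | 41 | 3 |
| V/I-free among core-4 amyloid | 16 | 18 | — |

Every individual disagreement with the published tables is a deciding
extreme of ±3 or ±7 milliunits and is boundary-flagged (e.g. `xxPQxx` and
`xxDQxx` have max +0.003 here, and the nonamyloid core-2 set instead
contains `xxEPxx`/`xxSPxx` at max −0.007; `MxVVxx` has min −0.007 under
hydrophobic wildcards). Each published count lies inside the bracket
obtained by shifting the decision threshold by the band, confirming the
rounding explanation. The structural zero-results are robust, not
boundary effects: no amyloid pattern with three fixed positions and no
nonamyloid pattern with five free positions exists, with deciding margins
beyond 30 milliunits.

## Synthetic fixtures

Test matrices are drawn with entries uniform on [−0.600, +0.300] and bias
on [0.500, 1.500] (milliunit steps), ranges bracketing the default matrix,
and are rejected (rarely) unless both labels are achievable, so oracle
comparisons are never vacuous. They emulate the additive structure and
magnitude of the real table but not its residue correlations (e.g. the
V/I/L enrichment of real amyloid columns), so passing oracle tests
demonstrates correctness of the bound/enumeration machinery, not biological
realism. Fixture generation, including peptide files with deliberate
errors, is fully determined by the seed.

## Numerical and interface choices

- Expansion streams enumerate substitutions in alphabetical residue order;
  all data outputs are timestamp-free and byte-deterministic.
- Peptide inputs: plain text (one per line, `#` comments) or FASTA; FASTA
  records longer than six residues are errors — the model is defined on
  hexapeptides, and silent sliding-window scoring would misrepresent it.
- Validation precedes computation; invalid inputs produce no partial
  output, and every problem is reported with its line number or record id.
- Brute-force classification (the enumeration oracle) refuses expansion
  spaces above a caller-supplied limit (default 10⁶).
- Oracle sweeps in the test suite restrict the fixed-slot residue pool and
  the wildcard alphabet (sizes ≤ 4) so that full per-candidate enumeration
  stays feasible; the vectorized miner is additionally checked against a
  full 20⁶ score-tensor reduction for the headline counts during
  development.

## Limitations

- Scores quantify distance from a rounded separating hyperplane; the
  underlying predictor's accuracy is ~84%, so "uniformly predicted
  amyloid" is a statement about the predictor, not about experimental
  aggregation.
- No sliding-window scoring of longer sequences; hexapeptides only.
- Counts near the decision boundary depend on unpublished weight precision;
  see the table above. The published headline counts for the core-4
  unrestricted and core-3 small-nonpolar sets differ from the
  exact-arithmetic ones by more than a handful of patterns (84 and 21,
  all boundary cases), which is irreducible without the original weights.
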