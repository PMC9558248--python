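# hexamyloid

Hexapeptide amyloid-propensity scoring and exhaustive mining of succinct
amyloid / nonamyloid sequence patterns.

Hexapeptides are the standard model system for studying amyloid formation:
short aggregation-prone segments nucleate the cross-β structure of amyloid
fibrils, and experimental datasets (e.g. the Waltz set of 514 amyloidogenic
and 901 nonamyloidogenic hexapeptides) have made it possible to train
classifiers for the amyloid state. A *linear* SVM classifier over
position-wise residue features collapses to something completely
transparent: a 20×6 **amyloid effect matrix** `M` and a bias `b`, with

    score(p) = Σ_{j=1..6} M[p_j, j] + b,      predict amyloid ⇔ score > 0

for a hexapeptide `p = p₁…p₆`. This package embeds that published matrix
(`b = 1.083`; entries like `M[I,3] = +0.26`, `M[P,1] = −0.56`) and works in
exact integer milliunits, so every score is reproducible to the last digit.

Because the score is additive over positions, a wildcard **pattern** such as
`xxPPxx` — fixed residues at some positions, free (`x`) positions
substituted independently from a chosen residue alphabet — can be certified
*uniformly* amyloid or nonamyloid for its entire hexapeptide space with two
O(1) bounds: substitute the per-column minimum (or maximum) at each free
position. `xxPPxx` has maximum score −0.167 ≤ 0, so all 20⁴ = 160 000
matching hexapeptides are predicted nonamyloid; `FxFLWx` has minimum score
+0.023 > 0, so all 400 matches are predicted amyloid. A pattern is
**minimal** when freeing any single fixed position destroys uniformity. The
miner sweeps all `Σₖ C(6,k)·20ᵏ = 21⁶ − 1 = 85 766 120` candidate patterns
(a few seconds, vectorized) and reports every valid or minimal pattern per
core size, including restricted wildcard alphabets (small nonpolar `GAST`,
hydrophobic `CVLIMPFYW`, polar `DENQHKR`, hydrophobic minus proline
`CVLIMFYW`, all minus proline).

## Worked example

```sh
$ echo IVIVIV | hexamyloid predict -
peptide score   label
IVIVIV  1.233   amyloid
```

The six matrix entries for I,V,I,V,I,V at positions 1–6 sum to 0.15; adding
`b = 1.083` gives 1.233 > 0, hence amyloid.

```sh
$ hexamyloid check FxFLWx
pattern alphabet core n_free expansion_count min_score max_score class           minimal boundary_flag
FxFLWx  all      4    2      400             0.023     0.853     uniform_amyloid true    false
```

The fixed slots contribute −0.16; the worst free-position substitutions add
−0.45 (column 2) and −0.45 (column 6); with the bias the minimum over all
400 expansions is 0.023 > 0, so every match is predicted amyloid, and no
single fixed slot can be freed without losing that guarantee (`minimal
true`). The `boundary_flag` column marks verdicts decided by less than
0.010 score units — the zone where the two-decimal rounding of the
published matrix can flip a verdict relative to the full-precision weights.

Mining all minimal nonamyloid patterns with two fixed residues:

```sh
$ hexamyloid mine --class nonamyloid --cores 2 --out nonamyloid2.tsv
$ grep -c -v '^#\|^pattern' nonamyloid2.tsv
24
```

The same machinery is available as a library (`hexamyloid.mine`,
`hexamyloid.classify_pattern`, …), and `hexamyloid fixtures --seed N` writes
seeded synthetic matrices and peptide files for testing.

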