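# hknot

Prediction of **H-type RNA pseudoknots** — including hairpin stem-loops
inside the pseudoknot loops — from a single RNA sequence, with the
evaluation machinery used to score such predictions at base-pair level.

An H-type pseudoknot is the simplest crossing structure in RNA: two stems
whose base pairs interleave, `i < k < j < l` for core pairs `(i, j)` and
`(k, l)`, joined by two loops. Those loops are not always unstructured:
they can carry hairpin stem-loops of their own, which most lightweight
pseudoknot predictors ignore. `hknot` searches for the two crossing *core
stems*, grows them outward with stacked pairs (allowing bulges and
internal loops), then looks for hairpins inside the remaining loop
sequence, and selects the final structure by **maximum base pairing,
then minimum free energy**. Output is extended dot-bracket notation, with
`(` `)` for the first stem plus all nested pairs and `[` `]` for the
crossing second stem.

The package is aimed at people studying small pseudoknotted RNAs
(viral frameshift elements, telomerase-like motifs, ribozyme fragments)
who want a transparent, fully inspectable prediction pipeline rather
than a black-box folding engine.

## The method

For a sequence *S* and tuning parameters *P*:

1. **Core-stem candidates.** Enumerate every pair of crossing,
   complementary base pairs `(i, j)`, `(k, l)` with `i < k < j < l`
   (A-U, G-C and the G-U wobble pair by default).
2. **Decoration.** Extend each stem outward with stacked pairs — stem 1
   pairs left-flank bases with right-loop bases, stem 2 pairs left-loop
   bases with right-flank bases — skipping up to `max_gap` bases per side
   at most `max_interruptions` times per stem (a bulge if one side, an
   internal loop if both).
3. **Filter.** Keep candidates within `stem_slack` (default 2) of the
   maximum pair count and order them by ascending free energy.
4. **Hairpins.** Search each survivor's loops for stacked hairpins
   (minimum 2 stem pairs enclosing a loop of ≥ 3 nt) and emit every
   with/without-hairpin variant (1, 2 or 4 per candidate).
5. **Selection.** Among all variants, keep the maximum total pair count
   and return the minimum-free-energy structure.

Energy is scored by a self-contained nearest-neighbor model (Turner-style
stacking constants, a monotone hairpin-loop cost table, a flat pseudoknot
penalty); any callable `(variant, sequence) -> kcal/mol` can be plugged
in instead. See `docs/methods.md` for the model, its assumptions and its
limits.

## Worked example

The 22-nt sequence `UCAAAUGGACAUAGCAUAACAU` folds into a pseudoknot with
a hairpin in its right loop:

```bash
$ hknot predict UCAAAUGGACAUAGCAUAACAU --trace
UCAAAUGGACAUAGCAUAACAU
((..[[[))..((...)).]]]
energy: 6.01 kcal/mol  time: 0.014 s
stage1  .(....[)...........]..
stage2  .(...[[)...........]].
stage2  .(..[[[)...........]]]
stage2  ((..[[[))..........]]]
stage4  ((..[[[))..((...)).]]]
```

Reading the rows: stage 1 finds the crossing core pairs C2-G8 and G7-C20;
stage 2 stacks U6-A21, A5-U22 onto stem 2 and U1-A9 onto stem 1; stage 4
adds the hairpin U12-A18 / A13-U17 (loop 14–16) inside the right loop.
The final structure has 7 base pairs and a computed free energy of
6.01 kcal/mol under the shipped parameter set.

The same API is available from Python:

```python
from hknot import parse_sequence, predict

result = predict(parse_sequence("UCAAAUGGACAUAGCAUAACAU"))
result.dotbracket   # '((..[[[))..((...)).]]]'
result.energy       # 6.01...
```

Other entry points: `hknot evaluate` scores predicted against reference
dot-bracket files (base-pair PPV / recall / F1 / MCC), and
`hknot simulate` writes planted-pseudoknot fixtures (FASTA + ground-truth
dot-bracket) for benchmarking.

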