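# lrtab

Support (log likelihood-ratio) and variance tests for contingency tables.

The same observed/expected pair in an r×c count table answers two distinct
questions, and they call for different statistics:

- **Are the binomial proportions equal?** Answered by the support
  `S = Σ O·ln(O/E)` and its chi-squared form, the likelihood-ratio test
  statistic `2S` (the G-test, right tail).
- **Is the model variance as expected?** Answered by Pearson's
  `X² = Σ (O−E)²/E` read against the *left* tail (a small p flags data that
  fit "too good to be true"), or by the support `Svar` for the best-fitting
  variance-inflation factor.

The package also provides:

- expected-value models from margins, from externally specified cell
  probabilities, or from fixed expected counts (`tables`);
- evidence grading of support values on the conventional strength-of-evidence
  scale, plus 2×2 effect sizes — odds ratio, risk ratio, risk difference
  (`evidence`);
- a closed-form 2×2 log likelihood-ratio oracle, the series expansion of S
  with its |O−E| < E validity diagnostic, Williams-corrected LRT, and the
  signed root of X² (`core`);
- fixed-margin statistic scans and seeded product-binomial Monte Carlo
  type-I/type-II error-rate comparisons between the LRT and X² (`simulate`);
- a CLI (`lrtab`).

## CLI

Analyse a table (inline `a,b;c,d` or a CSV/TSV path; header row and label
column are auto-detected):

```sh
lrtab test --table "80,9920;120,9880"                 # LRT + support + effects
lrtab test --table "3,997;10,990" --which both        # proportions and variance
lrtab test --table counts.csv --probs probs.csv --format json
```

Expected values default to the table's margins; `--probs FILE` scales a cell
probability matrix by N, `--expected-counts FILE` supplies expected counts
directly. `--which {proportions,variance,both}` selects the sections;
`--include-x2-proportions` additionally reports the right-tail X² test of
proportions with a caution (X² measures the model variance, not the
proportions).

Simulations:

```sh
lrtab simulate scan --margin 100 --expected-a 50          # LRT/X2/2*Svar trace
lrtab simulate errors --p1 0.1 --p2 0.05 --reps 50000 --seed 1
```

## Library

```python
import lrtab

table = lrtab.make_table([[3, 997], [10, 990]])
model = lrtab.expected_from_margins(table)

lrtab.lrt(table, model)              # 2S = 4.00, right-tail p = 0.045
lrtab.variance_x2_test(table, model) # X2 = 3.79, left-tail p
lrtab.svar(8.08, df=1)               # support for variance inflation
lrtab.grade_support(2.0)             # "moderate", LR = 7.4
lrtab.effect_sizes(table)            # OR = 0.30, RR, risk difference
```

## Conventions

- `0·ln 0 = 0` and `0/0 = 0` in cell terms, so empty cells and degenerate
  margins give finite, well-defined statistics; `O > 0` against `E = 0`
  yields infinite support, flagged rather than raised.
- `signed_root_x` is positive when the top-left cell exceeds its expectation.
- Degenerate tables (a zero row/column margin) have all statistics defined
  as 0 and carry a `degenerate` flag; in Monte Carlo runs such draws count
  as non-rejections and are tallied.
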