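# fragix

Fragility-index analysis for two-arm randomized controlled trials with
dichotomous outcomes.

A statistically significant trial result can hinge on a handful of outcome
events. The **fragility index (FI)** quantifies this: it is the minimum number
of participants in one arm whose outcome must be reclassified from non-event
to event — keeping arm sizes fixed — before a two-sided Fisher exact test of
the 2×2 table loses significance (p ≥ α, with α = 0.05 by default). The
**fragility quotient (FQ)** is FI divided by the trial's total randomized
sample size. A cohort of trials (for example, all RCTs in a clinical field
that reported significant results) can then be summarised by median FI/FQ,
compared across subgroups (Mann–Whitney U for two groups, Kruskal–Wallis for
three or more), and correlated with trial characteristics (Spearman's r_s).
The package is aimed at clinical meta-researchers running such fragility
reviews, and at trialists who want the FI of a single result.

What's inside:

- `fragix.exact` — exact 2×2 machinery: hypergeometric point probabilities
  and the two-sided Fisher exact test (minimum-likelihood rule), accumulated
  in exact integer arithmetic so behaviour at the 0.05 boundary is never a
  floating-point accident.
- `fragix.fragility` — the FI iteration, FQ, and the loss-to-follow-up
  comparison (NPLFU > FI flags trials whose unobserved outcomes alone could
  overturn significance).
- `fragix.corpus` — trial-corpus CSV schema, validation, and categorical
  derivations (publication-year bins, journal groups).
- `fragix.cohort` — median/IQR descriptives, subgroup contrasts, Spearman
  correlations, and the subgroup-table / histogram / scatter data products.
- `fragix.simulate` — a seeded generator of synthetic significant-trial
  corpora (1:1 binomial trials passed through the significance inclusion
  filter), so the whole pipeline is testable without external data.
- `fragix.cli` — the `fragix` command with `compute`, `batch`, `cohort` and
  `simulate` subcommands.

## Worked example

The fragility index of a trial with 0/5 events in the intervention arm and
5/5 in the control arm:

```sh
$ fragix compute --ei 0 --ni 5 --ec 5 --nc 0
{
  "fi": 2,
  "fq": 0.2,
  "p_initial": 0.00793651,
  "p_terminal": 0.166667,
  "modified_arm": "intervention",
  "exhausted": false
}
```

Reading: the table starts at p = 2/252 ≈ 0.0079. Moving one intervention
participant from non-event to event gives p = 12/252 ≈ 0.048 (still
significant); moving a second gives p = 42/252 ≈ 0.167 ≥ 0.05. So FI = 2 —
two reclassified outcomes overturn the result — and FQ = 2/10 = 0.2.

The same computation in Python:

```python
from fragix import ContingencyTable, fragility_index
fragility_index(ContingencyTable(0, 5, 5, 0))
# FragilityResult(fi=2, fq=0.2, p_initial=0.0079..., p_terminal=0.1666...,
#                 modified_arm='intervention', exhausted=False)
```

A full cohort pipeline on a synthetic corpus:

```sh
$ fragix simulate --n-trials 66 --seed 7 --out corpus.csv
66 trials written to corpus.csv
$ fragix cohort --corpus corpus.csv --out-dir report
report bundle written to report
```

`report/summary.json` then holds the cohort descriptives (for this seed:
66 trials, median FI 8.0 with IQR 3.25–19.75, median FQ 0.0408, median sample
size 234, 29 trials with NPLFU > FI), `report/table1.csv` the subgroup
contrasts with their Mann–Whitney/Kruskal–Wallis p-values, and
`report/fi_histogram.csv` / `report/fi_scatter.csv` the FI distribution and
the FI-vs-characteristic scatter data. `fragix batch` writes just the
per-trial FI/FQ table, and `fragix cohort` also works on your own extraction
table in the documented CSV schema (see `fragix.corpus`).

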