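# Methods

## The exact test and its two-sided convention

All fragility computations condition on both margins of the 2×2 table. Under
the null of no association, the intervention-arm event count X follows a
hypergeometric law with parameters (N total participants, K total events,
n intervention-arm size). The two-sided Fisher exact p-value uses the
**minimum-likelihood rule**: p is the sum of P(X = x) over every x in the
support whose point probability does not exceed that of the observed table.
This is the convention of mainstream exact-test implementations (including
the widely used online fragility calculators and `scipy.stats.fisher_exact`,
against which the implementation is cross-checked in the tests). Mid-p
variants, one-sided tests and chi-square approximations are deliberately out
of scope.

**Numerical choice — exact integer accumulation.** Point probabilities are
integer numerators C(K,x)·C(N−K,n−x) over the common denominator C(N,n),
built with a multiplicative recurrence in Python big-int arithmetic and
converted to a float by one correctly-rounded division at the end. The
obvious alternative (log-factorial accumulation with a relative tie
tolerance) fails exactly where fragility analysis is most sensitive: the
significance boundary. For example the table (0, 2; 12, 2) has p = 6/120 =
0.05 *exactly*; a log-gamma accumulation returns 0.049999999999999 87,
classifies the table as significant, and misreports FI = 1 instead of 0.
With integer arithmetic, point-probability ties in the two-sided sum and the
p ≥ α comparison are both exact (up to half an ulp of the true rational p,
far below the gap between distinct attainable p-values at trial-scale N).
The cost is negligible: the full grid of tables with arm sizes ≤ 20 is
evaluated in about a second.

## The fragility-index iteration

Starting from the observed table, one event is added to — and one non-event
simultaneously removed from — the arm that had the **smaller event count in
the original table**, so arm sizes and N are invariant at every step; the arm
choice is frozen for the whole iteration. FI is the smallest number of such
moves after which the two-sided exact p is ≥ α (default α = 0.05,
overridable). Properties and edge cases:

- **FI = 0** is a legal output: it occurs when the trial's own analysis was
  significant but the exact test on the 2×2 counts is not (test mismatch is
  common in real corpora).
- **Equal event counts.** The defining phrase "the arm with the smaller
  number of events" is ambiguous on ties; both directions are scanned and
  the smaller index returned (with the achieving arm recorded; on a complete
  tie the intervention arm is reported). This matches the "minimum number of
  events in either group" reading of the definition.
- **Exhaustion.** If the modifiable arm runs out of non-events while the
  result is still significant (e.g. a small all-events arm against a large
  low-risk arm), the result is flagged `exhausted` with `fi` = the number of
  non-events consumed, rather than raising. Exhausted results carry no
  meaningful FI; cohort summaries exclude them with a logged warning. The
  invariant "fi = 0 iff the initial p ≥ α" applies to non-exhausted results
  (an arm with zero non-events exhausts at fi = 0 while significant).
- FQ = FI / N, so FQ is monotone in FI at fixed N and lies in [0, 1].
- NPLFU > FI uses a strict inequality: only *more* lost-to-follow-up
  patients than the FI could overturn significance by themselves.

For trials reporting several significant outcomes, the corpus schema stores
one pre-selected 2×2 per trial (selection happens at extraction time);
`select_min_fi_outcome` implements the "smallest FI wins" rule for callers
who have all candidate tables.

## Cohort statistics

- **Quantiles.** Median and IQR use linear interpolation between order
  statistics at h = (n−1)p + 1 (numpy's default), the dominant convention in
  mainstream statistical environments; it produces half-integer medians
  (e.g. 149.5) for even n.
- **Subgroup contrasts.** Two groups: Mann–Whitney U from joint mid-ranks;
  exact enumeration when neither sample exceeds 8 and there are no ties,
  otherwise the tie-corrected normal approximation with a 0.5 continuity
  correction (scipy's `method="auto"`). Three or more groups: tie-corrected
  Kruskal–Wallis H with a chi-square tail on k−1 df; an all-identical input
  is defined as H = 0, p = 1 (scipy returns NaN there). Subgroups with fewer
  than 4 trials report a median but no IQR (quartiles from < 4 points are
  unreliable). Tri-state design flags (yes/no/unsure) are pooled to
  yes vs no-or-unsure for the subgroup table.
- **Correlations.** Spearman's r_s (Pearson correlation of mid-ranks,
  t approximation on n−2 df) of the FI against total sample size, total
  events, and the trial-reported p-value; pairs missing a reported p are
  dropped pairwise with a logged count, and a panel with fewer than 3 usable
  pairs is omitted with a warning.
- **No multiplicity adjustment** is applied across characteristics — each
  subgroup contrast is reported with its raw p-value, mirroring standard
  practice in fragility reviews; readers should interpret the subgroup
  p-values descriptively.

## The synthetic corpus generator

Fragility reviews sample *published significant trials*, so the generator
models exactly that: per trial it draws a shared arm size
(round(LogNormal(μ, σ)), floor 5 — 1:1 allocation), a control risk p₀ ~
U(0.10, 0.60), a risk ratio r ~ U(0.30, 0.90) applied to the intervention
arm (capped at probability 1), binomial event counts per arm, and **rejects
and redraws the whole trial until the two-sided exact p < α** — the
inclusion filter. Loss to follow-up is Binomial(2n, rate) with rate ~
U(0, 0.10); year, journal and design flags are categorical draws whose
weights follow a published 66-trial preterm-neonate cohort (multicenter
56.1%, double-blind 33.3%, registered 45.5%, ITT 59.1%, primary outcome
62.1%, journal shares 18.2/10.6/10.6/10.6/4.5/45.5%). The arm-size
parameters (μ = ln 74.75, σ = 1.10) put the *drawn* total-N median at ~150
with IQR spanning ~80–370, matching that cohort's extraction table.

What the generator does and does not emulate:

- Because the filter uses the same exact test as the FI computation, every
  accepted trial has FI ≥ 1 by construction. Real corpora contain FI = 0
  trials because the trial's own test (often an uncorrected chi-square)
  disagrees with the exact test; `reported_test="chi_square"` reproduces
  this mechanism by filtering on the uncorrected chi-square p instead.
- The significance filter selects for power, so the *accepted* trials are
  larger and less fragile than the raw draws (median accepted total N ≈ 270,
  median FI ≈ 9 at the defaults): a real selection effect, but it means the
  synthetic cohort is deliberately *not* tuned to reproduce any published
  cohort's headline medians. Passing tests therefore demonstrate correctness
  of the machinery and recovery of the qualitative structure (FI rising with
  sample size and total events, falling with reported p; strong effects in
  large trials less fragile than borderline effects in small ones), not
  distributional agreement with any particular literature sample.
- Multi-outcome trials, non-1:1 allocation and cluster randomization are out
  of scope (the 1:1 inclusion criterion excludes them).

Reproducibility: trial i uses the PRNG substream seeded by (root seed, i),
so growing a corpus never reshuffles earlier trials, and a corpus CSV is
byte-identical across runs of the same seed.

## Problem sizes in the verification suite

The exhaustive exact-test check enumerates every 2×2 table with N ≤ 60
against a strict integer-arithmetic oracle; the fragility check covers the
full grid of arm sizes ≤ 20 against a naive rebuild-and-retest oracle; rank
tests are compared with 10,000-draw permutation oracles at group sizes where
the analytic approximation error sits below the Monte-Carlo noise (tolerance
0.02 ≈ 4 MC standard deviations); direction-recovery checks use seeded
500-trial corpora. `scripts/acceptance.py` uses the same 500-trial size.

## Known limitations

- Only dichotomous outcomes: no continuous-outcome fragility, and no reverse
  fragility for non-significant results.
- Journal grouping is a fixed six-category label map; no impact-factor
  modelling.
- The generator's metadata (year, journal, flags) is drawn independently of
  trial size and effect, so metadata–FI subgroup differences in synthetic
  corpora are null by construction; subgroup machinery is validated on
  structure and test routing, not on recovering metadata effects.
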