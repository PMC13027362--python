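# Methods

## The screening model

`inversepv` implements a case/non-case disproportionality screen over a
spontaneous-report database. For each drug, deduplicated reports are
cross-classified by exposure (the drug appears in the report under any role
code) and occurrence of the target event (the report lists at least one of
the target MedDRA preferred terms, matched case-insensitively after
trimming), giving the 2×2 table (a, b, c, d). The screen computes

- the reporting odds ratio `ROR = (a·d)/(b·c)`,
- the Woolf confidence interval
  `exp(ln ROR ± z · √(1/a + 1/b + 1/c + 1/d))`, with `z` the two-sided
  normal quantile at the configured level, evaluated at full precision
  (1.959964… at 0.95, never the rounded 1.96),
- a raw p-value from the two-sided Fisher exact test (sum of hypergeometric
  point probabilities not exceeding that of the observed table), and
- Benjamini–Hochberg adjusted p-values across the tested family.

A drug is an **inverse signal** when `ROR < 1`, `p_adj < alpha` and
`a ≥ min_cases` (plus `ci_high < 1` in `strict_ci` mode). The default
`min_cases = 40` is deliberately conservative: inverse signals are far more
sensitive to small-number instability than classical safety signals, so the
screen trades sensitivity for estimate stability. The default target event
set is the two preferred terms `Ulcerative colitis` and `Crohn's disease`,
treated as one composite inflammatory-bowel-disease outcome.

Exposure counting is role-agnostic (suspect, secondary suspect,
concomitant and interacting mentions all count). Restricting to suspect
drugs would bias an inverse screen: a drug that genuinely protects is
unlikely to be labelled causative in a spontaneous report.

## Design choices that were genuinely open

- **BH family.** The family adjusted by BH is, by default, the set of drugs
  passing the `min_cases` threshold (filter-then-adjust). The alternative
  (adjust across all drugs, then filter) is available via
  `adjust_then_filter=True`. The filter is a data-volume criterion, not a
  significance criterion, so applying it before multiplicity adjustment does
  not invalidate FDR control within the tested family.
- **Raw p-value.** Fisher's exact test is the default because the screened
  tables can have a small `a` even above the case threshold; a Pearson
  chi-square without continuity correction is available via
  `p_method="chi2"`.
- **Zero cells.** If any cell is zero, 0.5 is added to all four cells
  (Haldane–Anscombe) for the ROR and its CI only; the exact test always
  uses raw counts. Corrected rows carry a `corrected` flag. With the
  default case threshold, `a ≥ 40 > 0` for every family member, so the
  correction can only ever touch `b`, `c` or `d`.
- **Inverse criterion.** The default flag requires the point estimate below
  1 and `p_adj < alpha`; `strict_ci` additionally requires the upper CI
  bound below 1. The packaged reference candidates all satisfy the stricter
  criterion.
- **Unresolvable drug names.** A mention whose normalized key is marked
  UNRESOLVABLE in the lexicon — or is absent from the lexicon altogether
  (audited under a separate counter) — is dropped at mention level; the
  report is dropped only when every mention fails, preserving the broader
  background case set. A report with no drug mentions at all is kept as
  background (it contributes to cells c/d only).
- **Version ties.** Case-version deduplication keeps the highest version
  per case id; a tie (which compliant extracts should not contain) breaks
  deterministically toward the lexicographically greatest report id.
- **Name-key normalization** uppercases, strips punctuation (keeping `+`,
  `-` and word characters), collapses whitespace, and repeatedly removes
  trailing dosage tokens (`20MG`, `20 MG`, …) and dose-form words
  (TABLET/CAPSULE/INJECTION/…). It is a deterministic, test-coverable
  stand-in for production normalization pipelines backed by curated drug
  dictionaries; it does no fuzzy matching or spelling correction.

## The synthetic reporting system

`simulate.SimConfig` defines a generative model of an ICSR stream:

- each of `n_cases` cases is exposed to each of `n_drugs` drugs
  independently with probability `exposure_prob` (default 0.05, a typical
  order of magnitude for a widely used drug's share of reports);
- the odds of the target event are the baseline odds
  (`baseline_event_prob`, default 0.05) multiplied by `planted_or_j` for
  every exposed drug j — effects combine multiplicatively on the odds
  scale, which is what makes the marginal report-level ROR estimate the
  planted value and recovery testable;
- exposures are written under verbatim spellings drawn uniformly from
  per-drug variant lists (brand, salt, dosage-suffix and case variants);
  when every constituent of a configured combination product is exposed,
  the combo verbatim replaces the constituents' individual mentions;
- role codes are uniform over {PS, SS, C, I}, since the screen is
  role-agnostic and roles only exercise plumbing;
- noise events are drawn from a fixed synthetic vocabulary
  (`PT_0001`…`PT_0500`) that can never collide with a target term;
- with probability `duplicate_fraction` a case emits an extra superseded
  version-1 row that deduplication must discard.

All draws come from one `numpy.random.Generator` in a fixed order, so an
identical config produces byte-identical files. The generator does **not**
model demographics, dates, reporter countries, cross-manufacturer duplicate
cases, channeling bias, co-reporting distortion or confounding by
indication. Passing tests therefore demonstrate that the *procedure* is
correct and calibrated under an idealized reporting model — not that
inverse signals from real spontaneous reports are unconfounded.

`direct_count_simulation` is a count-level shortcut used by the calibration
studies: it draws the exposed margin Binomial(n, exposure_prob) and the two
event counts binomially within margins, which is marginally equivalent to
materializing reports. A smoke test compares the two paths' log-ROR
distributions to guard against drift.

## Calibration studies and problem sizes

- **Null FDR**: 2,000 independent drug–event pairs with all odds ratios 1,
  50,000 reports each, 20 replicates; the mean fraction of tested drugs
  flagged at `alpha = 0.05` must stay below alpha plus three Monte-Carlo
  standard errors. (Fisher's test is conservative at these cell sizes, so
  the realized fraction is far below the bound.)
- **Coverage**: 1,000 count-level replicates at planted OR 0.3 with all
  expected cells above 50; the 95% Woolf interval should cover the planted
  value in 93–97% of replicates. With near-zero expected cells coverage
  degrades; the report flags this (`small_cells`) rather than asserting it
  away.
- **Recovery**: planted OR 0.056 — the magnitude of the strongest published
  inverse signal — at 200,000 reports, 100 replicates; the geometric mean
  of the estimates must land within 10% and the inverse flag must fire in
  over 90% of replicates. The summary estimate is the geometric mean
  (`exp` of the mean log-ROR), the natural location summary for a
  log-scale estimator.

Monte-Carlo tolerances in the test suite are always computed from the
replicate counts in play, never hard-coded margins.

## The packaged reference candidates

`data/reference_candidates.tsv` holds the 73 published repurposing
candidates for inflammatory bowel disease (drug, ROR, 95% CI bounds) in
ascending ROR order. Only summary statistics are available — not the
underlying 2×2 counts — so these rows carry no p-values or case counts and
are used for funnel and consistency checks only:

- every row's `√(ci_low · ci_high)` reproduces its printed ROR at three
  decimals (the Woolf geometric-mean identity), a strong internal
  consistency check on the published table;
- the packaged feasibility config (empty, because the table is already
  post-feasibility) keeps all 73;
- the packaged class map annotates every candidate with a therapeutic
  class; the designated immune-mediated/immunomodulatory classes select
  exactly the nine prioritized drugs (lenalidomide, dupilumab,
  cyclophosphamide, fingolimod, dimethyl fumarate, apremilast, imatinib,
  glatiramer acetate, interferon beta-1a).

Feasibility exclusions and class designations are clinical judgments that
no algorithm can reproduce; they enter the pipeline only as declarative,
versioned configuration with mandatory reason logging, and users supply
their own lists for other diseases. The packaged configs guarantee the
endpoint counts (73 → 9), not any intermediate stage-by-stage breakdown.

## Known limitations

- The screen estimates reporting disproportionality, not risk or benefit;
  an inverse signal may reflect prescribing patterns, comorbidity
  structure, channeling or reporting behavior rather than protection.
  Nothing here adjusts for covariates.
- The MedDRA hierarchy is not modelled; events are flat preferred-term
  strings.
- Multi-quarter FAERS merging, live openFDA queries and
  RxNorm/DrugBank-backed normalization are out of scope; the lexicon format
  replaces them.
- `exact_p` delegates to `scipy.stats.fisher_exact`; the test suite holds
  it to the hypergeometric-enumeration definition (relative tolerance
  1e-7) exhaustively for small tables and on random tables up to N = 200.
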