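# inversepv

Inverse pharmacovigilance signal screening on FAERS-style spontaneous
adverse-event reports, for drug-repurposing hypothesis generation.

Classical pharmacovigilance asks which drugs are reported *more* often with
an adverse event than expected. This package asks the opposite question:
which drugs are reported *less* often with a disease than expected — an
**inverse signal** that may hint at a protective or disease-modifying
association worth testing. It implements the full screen for the motivating
use case (inflammatory bowel disease, i.e. the MedDRA preferred terms
*Ulcerative colitis* and *Crohn's disease*) while keeping every threshold,
event set and filter configurable.

The pipeline:

1. **ingest** — parse `$`-delimited DEMO/DRUG/REAC tables, apply FDA case
   version control (per case, only the highest version survives), normalize
   verbatim drug names (brands, salts, dosage suffixes) to active
   substances through a lexicon, decompose combination products, and audit
   every row exactly;
2. **signal statistics** — for each drug build the report-level case/non-case
   2×2 table against the target event set and compute the reporting odds
   ratio `ROR = (a·d)/(b·c)`, its Woolf CI
   `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, a two-sided Fisher exact p, and
   Benjamini–Hochberg adjusted p-values; flag inverse signals
   (`ROR < 1`, `p_adj < 0.05`, `a ≥ 40` by default);
3. **funnel** — apply declarative feasibility exclusions and a
   therapeutic-class restriction with a fully reconciled audit trail, and
   export ranked candidate and forest-plot tables;
4. **simulate / calibrate** — a synthetic report generator with planted
   odds ratios, duplicates and messy drug names stands in for FAERS, and
   simulation studies measure the screen's false-flag rate, CI coverage and
   parameter recovery.

## Worked example

Simulate a small reporting system with one planted inverse signal
(odds ratio 0.2 on drug 0), then screen it:

```python
import inversepv as ipv

cfg = ipv.SimConfig(
    n_cases=5000, n_drugs=5, exposure_prob=0.1, baseline_event_prob=0.1,
    planted_or=(0.2, 1, 1, 1, 1), duplicate_fraction=0.2, seed=7,
)
rows, truth = ipv.generate_cases(cfg)          # 6019 raw rows, 5000 cases
ipv.write_faers_tables(rows, "data/")

lexicon = ipv.DrugLexicon(cfg.default_lexicon_entries())
cases, audit = ipv.ingest_directory("data/", lexicon)
# audit: 6019 input rows, 1019 superseded versions removed, 5000 cases kept

tables = ipv.build_tables(cases, ipv.DEFAULT_EVENT_PTS)
for r in ipv.screen(tables, ipv.ScreenConfig(min_cases=5)):
    print(f"{r.ingredient}  a={r.table.a:>3}  ROR={r.ror:.3f} "
          f"({r.ci_low:.3f}, {r.ci_high:.3f})  inverse={r.inverse_flag}")
```

```
DRUG_0000  a=  7  ROR=0.136 (0.064, 0.288)  inverse=True
DRUG_0001  a= 39  ROR=0.871 (0.618, 1.227)  inverse=False
DRUG_0003  a= 39  ROR=0.970 (0.688, 1.368)  inverse=False
DRUG_0004  a= 42  ROR=0.990 (0.710, 1.381)  inverse=False
DRUG_0002  a= 48  ROR=1.110 (0.810, 1.522)  inverse=False
```

The planted drug is recovered as the only inverse signal (its CI excludes
1); the four null drugs straddle 1. The same flow is available from the
shell — `inversepv simulate`, `inversepv screen`, `inversepv calibrate`
and `inversepv fixtures`, each driven by a JSON config and writing a
resolved-config copy, a run log and a funnel audit next to its outputs.

The packaged reference table (`inversepv fixtures`) carries the 73
published IBD repurposing candidates with their RORs and 95% CIs; the
packaged class map selects the nine immunomodulatory candidates from it,
lenalidomide (ROR 0.056, 95% CI 0.043–0.073) being the strongest inverse
association.

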