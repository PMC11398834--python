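# Methods

## The screening problem

Spontaneous-reporting databases collect case reports of suspected
adverse drug events without denominators: there is no count of exposed
patients, only of reports. Disproportionality analysis works around
this by asking whether a drug–event pair is reported *more often than
expected* given the drug's and the event's overall reporting
frequencies in the same database. tnfvigil implements this screening
for report sets shaped like the FDA Adverse Event Reporting System
(FAERS), restricted to reports with rheumatoid arthritis as the sole
indication and one of five TNF-α inhibitors as the primary-suspect (PS)
drug.

A flagged pair is a *signal of disproportionate reporting*, not a
causal claim: reporting is voluntary, selective, and confounded by
indication, publicity and reporting fashion.

## Cleaning model

- **Deduplication.** FAERS carries a case identifier and a version; a
  case re-reported or corrected appears as several versions. The
  package keeps, per case, the highest version (ties broken by last
  occurrence), which is the standard "latest version wins" rule. The
  operation is idempotent and order-stable.
- **Drug-name normalization.** PS drug spellings are folded to lower
  case, trimmed, and looked up in a packaged synonym dictionary mapping
  trade names and biosimilar names to the five canonical molecules.
  Unmatched names are never dropped silently: they keep their raw
  (lower-cased) spelling and are marked unmatched, so the subsequent
  drug filter is auditable.
- **Inclusion filters**, applied after dedup in the order drug →
  indication → reporter, with each report charged to the first
  criterion it fails: (1) PS drug is a study drug; (2) the normalized
  indication set is *exactly* {rheumatoid arthritis} — a literal
  reading of a sole-diagnosis requirement, with a small indication
  synonym table ("RA" etc.); (3) the reporter is a physician,
  pharmacist or other health professional. The filter log records
  per-criterion attrition; retained + removed = input always holds.
- **Background pool.** Reports that pass the indication and reporter
  criteria but have a non-study PS drug form the comparator pool. By
  default the denominator of every 2×2 table is this cleaned
  same-indication extract (plus the other study drugs); a config switch
  restricts the comparator to the other study drugs only.
- **Time to onset (TTO)** is event date minus therapy start in whole
  days. Gaps over 720 days are excluded from onset summaries only — the
  report still counts for disproportionality. Negative gaps are data
  errors and likewise excluded from onset summaries. Missing dates
  propagate as missing.

## Statistics

For a 2×2 table (a, b, c, d), N = a+b+c+d, E = (a+b)(a+c)/N:

- **ROR** = ad/bc with Woolf's log-scale CI. Zero cells get the
  Haldane–Anscombe +0.5 added to all four cells and the row flagged;
  a = 0 tables can never be signals anyway because of the count
  threshold.
- **IC** = log2((a+0.5)/(E+0.5)), the shrinkage form of the Bayesian
  confidence propagation neural network information component. The
  default lower bound is the closed-form approximation
  IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2), which approximates
  the 2.5% quantile of the Gamma(a+0.5) posterior of the
  observed-count intensity; the `gamma` variant computes that quantile
  exactly, and the `bate` variant implements the classical Beta-prior
  posterior mean with a normal-approximation bound. The test suite
  cross-checks the closed form against Monte-Carlo sampling of the
  Gamma posterior (agreement ~0.1 bits at moderate a) and the ROR CI
  against statsmodels' independent implementation.
- **p-values**: Yates-corrected chi-square by default, automatic
  fallback to Fisher's exact test whenever any expected cell is below
  5; degenerate margins give p = 1. Fisher is validated against full
  hypergeometric enumeration for small margins.
- **Multiplicity**: Bonferroni within the family of distinct events
  tested for the same (drug, stratum) — matching per-drug signal lists.
  Which test the correction gates is genuinely underdetermined in this
  workflow's literature, so the adjusted p is always reported but does
  not enter the signal verdict unless `require_significance` is set.
- **Verdict**: ROR025 > 1 AND a > 3 (strict, configurable) AND
  IC025 > 0. The strict `a > 3` follows the stated screening rule;
  the threshold is a parameter because practice varies between "> 3"
  and "≥ 3".

Sex stratification repeats the whole construction inside the female and
male substrata; unknown-sex reports contribute only to the "all"
stratum, so female-N + male-N ≤ all-N.

## Synthetic-report generator

The generator emulates the FAERS quarterly layout: six "$"-delimited
relations (DEMO, DRUG, REAC, OUTC, THER, INDI) keyed by case and report
identifiers. Per report it draws a PS drug, sex / age / weight /
country / reporter occupation, K event terms (K truncated-geometric
with mean 2, max 10; draws with replacement de-duplicated into a set),
outcome codes, a therapy start uniform over a 20-quarter window, and an
event date offset by a per-drug lognormal gap with a configurable
fraction forced beyond 720 days. Nuisance processes: duplicate case
versions (some with ±1 kg weight perturbation, to force version-based
rather than exact-row dedup), missing demographics and dates, trade-name
spellings of the PS drug, and non-RA or multi-indication cases.

Signals are planted multiplicatively: for an injected (drug, event,
lift λ) the per-draw event probability is λ × background weight,
renormalized over the vocabulary, with optional per-sex multipliers.
`injected_event_probability` / `report_event_probability` give the
closed-form targets used as oracles for injection fidelity.

Default study conditions (`default_scenario`): the five study drugs
carry marginal reporting probabilities proportional to the real
per-drug report counts of the published RA extract
(3441 : 918 : 1190 : 15730 : 1432) and together make up half of all
reports; ten common RA co-medications share the other half. The event
vocabulary has ~40 background terms with Zipf-like weights plus rare
signal terms. Four class-effect events are planted in all five drugs
(lift 10) and two or three unique events per drug (lifts 12–25),
one with a strong female bias, so the set decomposition has a known
4-common / unique-per-drug ground truth. Nuisance defaults: 5%
duplicates, 8% missing sex, 30% missing age, 70% missing weight
(matching the real extract's weight missingness), 10% missing dates,
30% trade-name spellings, 80% RA-only indication, 75% female.

What the generator does **not** model: reporting trends over time,
country-specific reporting cultures beyond a categorical label, event
term hierarchies/synonymy (terms are opaque strings), correlated event
co-occurrence beyond shared drug lifts, and exposure denominators.
Passing tests therefore demonstrate the pipeline's correctness and its
operating characteristics under idealized multiplicative signals — not
performance on real FAERS data, where duplicates are messier and
confounding is real.

## Operating characteristics (computed by the test suite)

- With unique-event injections (`recovery_scenario`: clean comparators,
  lifts ≥ 10, expected with-drug count ≥ 10) at 50,000 reports, all
  planted pairs are flagged in 20/20 replicate seeds.
- Under the null (`null_scenario`), the flagged fraction among pairs
  with E ≥ 1 pools to ≈0.9% over ten 50,000-report replicates — the
  joint ROR∧count∧IC criterion is conservative. Single replicates
  fluctuate by a few tenths of a percent around this.
- **Class-effect attenuation.** When the same event is lifted in *all*
  study drugs, each drug's comparator contains the other lifted drugs,
  so the observable ROR saturates at roughly 1/(lifted share of the
  comparator) no matter how large the lift. In the default scenario the
  largest drug dominates the study half of the extract, which caps the
  class-effect ROR near 2 for the smaller drugs; recovery of the
  planted common events is therefore reliable for a majority of drugs
  but not guaranteed 5/5 at this scale. This is a real property of
  within-extract comparators, not a generator artifact, and it is why
  the structural fixture assertions require majority recovery for
  class-effect events and exact behavior only for unique injections.

## Numerical and design choices

- Percentages in descriptive tables are 100·count/N rounded half-up to
  one decimal (decimal arithmetic, not banker's rounding), so every
  printed cell reconstructs exactly from its count and N.
- Age bins ≤17 / 18–64 / 65–85 / ≥86 are integer-year inclusive;
  fractional ages are floored. Weight bins <50 / 50–100 / >100 kg take
  both endpoints into the middle bin. Missing values pool under
  "uncertain".
- Outcome proportions use reports-with-any-outcome as denominator; a
  report with several outcome categories counts once in each, so
  proportions can sum past 100%.
- Problem sizes: law-of-large-numbers generator checks run at 10⁵
  reports (3 SE tolerance); oracle-equivalence checks at ≤1,000
  reports; the recovery and null studies at 50,000 reports ×
  20 / 10 seeds.
- The pipeline manifest records a configuration hash, input checksums
  (file mode), and row counts at every stage; identical config + seed
  give byte-identical manifests.

## Limitations

- Event terms are opaque strings: no MedDRA hierarchy, no synonym
  merging across terms, so split reporting of one clinical concept
  dilutes its signal.
- The comparator is the cleaned same-indication extract, not the whole
  database; this controls indication confounding but causes the
  class-effect attenuation above and makes signals relative to other
  RA treatments.
- No probabilistic record linkage: duplicates are recognized only via
  the case identifier.
- PRR, EBGM/MGPS, LASSO-based and time-scan methods are out of scope.
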