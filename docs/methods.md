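# Methods

## Scope and data model

The package re-evaluates literature-curated variants in *APP*, *PSEN1* and
*PSEN2* under the 2015 ACMG-AMP framework. A variant record carries its
identity (gene, protein-change label, variant type, transmembrane-domain
location, exon label), the classification reported by the source
literature before re-evaluation, and three annotation blocks: population
allele frequencies (ESP6500, 1000 Genomes, ExAC), in-silico predictor
verdicts (SIFT, PolyPhen-2, LRT, MutationTaster, MutationAssessor, FATHMM,
PROVEAN, CADD, REVEL and Reve for missense; GeneSplicer and Human Splicing
Finder for splice variants), and functional-study outcomes on amyloid-β
readouts. Protein-change strings are opaque labels: the analysis reasons
at the residue-label level, so no HGVS parsing or genomic-coordinate
arithmetic is performed, and frequencies/verdicts are inputs rather than
live database lookups.

## Evidence engine

Criteria are split into computed and curated. Computed:

- **PM2** fires iff the variant is absent from all three frequency
  sources. Because the genes are dominant, absence from general-population
  databases is moderate pathogenic evidence.
- **BA1** fires at a maximum observed allele frequency ≥ `ba1_min`
  (default 0.05, the standard stand-alone cutoff); otherwise **BS1** at
  ≥ `bs1_min`. No published BS1 cutoff exists for these genes; the default
  0.001 is configurable and deliberately conservative (roughly two orders
  of magnitude above the most common credible dominant-AD allele).
- **PP3** requires every *available* tool to call the variant damaging;
  **BP4** mirrors it with unanimous benign calls (the framework lists BP4
  as applicable but no trigger is specified, so the mirrored consensus is
  this package's choice). Tools reporting "unavailable" are excluded from
  the denominator rather than counted as disagreement, since aggregated
  predictor coverage varies by variant. A variant with no verdict at all
  is "not assessable": the engine assigns neither code rather than
  erroring, so sparsely annotated rows still classify.
- **PS3** requires ≥1 study showing increased total Aβ or an increased
  Aβ42/Aβ40 ratio and none showing no effect; **BS3** requires all (≥1)
  studies to show no effect; conflicting studies yield neither code.

Everything else (PVS1, PS1–2, PS4, PM1, PM4–6, PP1–2, PP5, BS1, BS4, BP3,
BP5–7) is curator-supplied. PVS1 is never auto-derived — loss of function
is not an established AD mechanism for *APP* — but frameshift, splicing
and CNV variants lacking a curated PVS1 are logged as candidate nulls.

The applicability filter removes PM3 (a recessive-disease criterion), PP4
(an AD family history is not a highly specific phenotype), BS2 and BP2
(incomplete early-age penetrance defeats healthy-carrier logic) and BP1
(missense is the primary mechanism), leaving 23 usable codes. Mutual
exclusions hold by construction: the frequency rules emit at most one of
PM2/BA1/BS1, consensus one of PP3/BP4, functional one of PS3/BS3. One
genuine conflict can arise — a curated BS1 on a variant absent from every
source — and is resolved in favour of the computed absence (the BS1 is
dropped with a warning), since both cannot be true of the same variant.

An optional residue-range table (gene → 1-based inclusive TM intervals)
can fill a missing domain column from the protein-change label; an
explicit input column always wins.

## Combining rules

The categorical 2015 rule table is encoded as minimum-count requirements
over strength classes only (PVS/PS/PM/PP/BA/BS/BP), serialized in config
so alternative tables can be tested. Classification is strict about
contradiction: any co-occurrence of pathogenic- and benign-side codes is
VUS, with no strength-weighted arbitration and no Bayesian point system.
When several rules fire, Pathogenic takes precedence over Likely
pathogenic and Benign over Likely benign. The engine is validated against
an independently coded literal transcription of the rules over every
realizable per-class count vector within (PVS ≤ 1, PS ≤ 4, PM ≤ 5, PP ≤ 4,
BA ≤ 1, BS ≤ 3, BP ≤ 5) — 14,400 vectors, of which 11,832 are realizable
as concrete code sets; the remainder require mutually exclusive codes on
both sides and are contradictory VUS by definition. PP5/BP6 are honored as
ordinary supporting codes despite their later deprecation, matching the
framework version implemented.

## Cohort statistics

- Per-gene P/LP fractions and the prior-classification concordance
  (fraction of previously-pathogenic variants still P/LP) are reported as
  percentages rounded half-up to two decimals, with raw numerator and
  denominator.
- Gene-spectrum comparisons use the Pearson chi-square: Yates-corrected on
  2×2 tables, uncorrected with df = r−1 for r > 2. The 2×2 statistic is
  computed by the closed form N·(max(0, |ad−bc| − N/2))²/(r1·r2·c1·c2):
  the explicit floor keeps the corrected statistic at zero when the
  correction would overshoot, which scipy's implementation does not
  guarantee; scipy cross-checks the regular region in tests.
- Variant-type comparisons are computed among P/LP variants only, with the
  two-sided Fisher exact test (sum of hypergeometric probabilities not
  exceeding the observed table's — the R-style definition), delegated to
  `scipy.stats.fisher_exact` and verified against exact integer
  enumeration for all tables with N ≤ 40.
- TM vs non-TM contrasts (domain = NA excluded) are reported under Yates,
  plain chi-square *and* Fisher, and under two definitions of the
  non-P/LP column (all other tiers; VUS only). Small cells make the
  method choice consequential, and the published values for these
  contrasts are not all derivable from a single method, so the panel
  reports all of them labeled rather than silently picking one.
- p-values print in scientific notation at three significant digits; raw
  doubles are kept in the machine-readable JSON.

## Synthetic cohorts

`generate_cohort` materializes per-cell (gene, type, domain, tier) target
counts. Evidence sampling is rule-directed, never rejection-based: a code
template satisfying the target tier is drawn from a per-tier pool filtered
by variant-type compatibility (PVS1 only on frameshift/splicing/CNV,
PP3/BP4 only where predictors exist, PM1/PM5 only on missense, PM4/BP3
only on indels), then annotations are constructed so the evidence engine
re-derives exactly that profile: PM2 ⇒ all frequencies absent; BA1 ⇒ a
frequency above the stand-alone cutoff; BS1 ⇒ between the cutoffs; no
frequency code ⇒ a tiny nonzero frequency; PP3/BP4 ⇒ unanimous verdicts;
neither ⇒ deliberately conflicting verdicts; PS3/BS3 ⇒ one synthetic assay
with the corresponding Aβ effect. Optional "noise" adds redundant curated
codes with a given probability, each kept only if the classification is
unchanged. Every generated variant is closed-loop checked (engine +
combiner reproduce the cell's tier) at generation time.

The deterministic 452-variant benchmark cohort fixes the cell histogram of
the published three-gene re-evaluation spectrum (66 *APP*, 323 *PSEN1*,
63 *PSEN2*), embeds prior-classification labels reproducing the published
per-gene concordance counts (279/287, 30/31, 8/16), rotates the three VUS
mechanisms (conflicting in-silico verdicts, benign functional data, plain
insufficiency) across VUS cells, and includes *PSEN2* T122R verbatim with
evidence {PM2, PM5, PP3}. Where the published cross-tabulation and the
per-gene narrative totals disagree, the narrative totals win and every
reallocated cell is listed in the cohort metadata (see
`reference_metadata()`); likewise the published per-type P/LP compositions
(which sum to 286 for *PSEN1*, not 288) are used directly as the input
tables for the variant-type tests rather than being forced onto the
cohort. The generator's seed varies annotation details (frequencies,
assay effects, noise codes) but never the histogram, priors or

classifications.

What the synthetic cohort does *not* emulate: real allele-frequency
spectra, realistic per-variant curated-evidence distributions (the true
historical evidence is unpublished; synthetic profiles are representative
templates), residue-level biology of the protein-change labels, or
correlations between annotation blocks. Passing tests therefore
demonstrate the correctness of the evidence rules, combiner and
statistics on cohorts with the published structure — not the fidelity of
any individual synthetic variant record.

## Numerical and design choices

- Percentages round half-up at two decimals (display); raw fractions are
  preserved everywhere.
- A chi-square on a table with observed = expected returns statistic 0,
  p = 1 exactly; zero margins are rejected as errors.
- Estimator classes (`EvidenceAssigner`, `ACMGClassifier`) follow the
  scikit-learn contract — `fit` validates and freezes configuration into
  trailing-underscore attributes, learns nothing — so the deterministic
  rule engine composes with sklearn pipelines.
- The domain (TM/nonTM/NA) of UTR and CNV variants is NA; they are
  excluded from all TM statistics.
- Known limitations: no VCF/coordinate support, no segregation inference,
  no criterion-strength modulation (e.g. PS at moderate strength), no
  gene-specific ClinGen specifications, no multiple-testing correction in
  the panel (none is part of the reproduced analysis).
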