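# Methods

## The mapping model

A phecode map is a relation from source codes (ICD-10-CM or WHO ICD-10)
to phecodes, assembled as the union of independent routes through
crosswalk resources and then resolved. The package treats each resource as
a directed edge table over typed code spaces (ICD-9-CM, ICD-10, ICD-10-CM,
UMLS CUI, SNOMED CT, OHDSI concept id, phecode) and each route as a fixed
chain shape over those tables:

* path A joins code descriptions to phecode descriptions after
  lowercasing and whitespace trimming — exact equality only, no
  punctuation stripping or fuzzy matching;
* path B joins the GEMS ICD-10-CM→ICD-9-CM crosswalk to the ICD-9-CM
  phecode map; equivalent (flag 0) and approximate (flag 1) entries both
  participate, trading some precision for coverage;
* path C chains ICD→CUI→ICD-9-CM equivalences (ICD-10-CM only, on by
  default, exposed as a flag);
* paths D/E/F chain ICD→CUI→SNOMED CT and then bridge SNOMED to ICD-9-CM
  via NLM rule maps, OHDSI concept relationships, or UMLS equivalences.
  OHDSI bridges may pass through internal concept-id→concept-id
  relationships; these are followed breadth-first to a hop limit of 5
  with cycle detection (the canonical chain uses two internal hops;
  unbounded traversal of a relationship graph risks cycles). NLM
  one-to-many entries are excluded by default (`include_nlm_one_to_many`
  reverses this), keeping only the one-to-one/many-to-one rule maps.

No precedence orders the paths: duplicates by (source, phecode, path)
merge their provenance chains, and distinct paths to the same pair remain
distinct rows so the evidence for each mapping stays auditable. WHO
ICD-10 uses paths A/D/E/F only — no GEMS exists for it, and the CUI
shortcut is treated as CM-specific.

### Hierarchy resolution

The phecode hierarchy is defined purely by the id string: `a` is a strict
ancestor of `b` iff the integer parts are equal and `b`'s digit sequence
(decimal point removed, leading zeros preserved) strictly extends `a`'s.
This reproduces every parent/child relation the phecode system exhibits
(401/401.1, 250/250.2/250.23, the 008 group) without an explicit parent
table, supports arbitrary depth, and makes leading-zero phecodes ("008")
safe because they are never converted to numbers except inside range
checks. Resolution removes, within one source code's candidate set, every
phecode that is a strict ancestor of another candidate — transitively, so
a grandparent falls to any retained descendant — and keeps all candidates
from unrelated families. The operation is idempotent and output-minimal;
`build_map` re-audits the no-ancestor-pair invariant after every build.

Codes are stored dotted; undotted input is accepted with
vocabulary-specific dot insertion (after 3 characters for ICD-10/10-CM and
numeric/V ICD-9-CM codes, after 4 for ICD-9-CM E-codes), since both
dialects occur in real exports. Canonicalization is idempotent.

## Phenotyping

Case counting uses distinct calendar dates, not raw rows, so same-day
duplicate billing never changes case status; `min_code_count` defaults
to 1 ("at least one code"), configurable because ≥2 is common PheWAS
practice. A prefix target denotes the phecode itself plus all string
descendants. Exclusion ranges are closed numeric intervals attached to
each phecode definition; carriers of any in-range phecode who are not
themselves cases are removed from the control pool. Case status takes
precedence over exclusion because exclusion ranges normally contain the
target phenotype. Every cohort build asserts the partition identity
(cases + controls + excluded = population) and control purity.

## Coverage and reproducibility

Coverage partitions the union of official and observed codes into
official × used × mapped cells (used-but-unofficial codes — local or
supplementary codes — get their own cells), tallies distinct
patient/date/code instances, and reports percentages rounded to two
decimals. The instance identity (mapped + unmapped = total) is asserted
against the event-mapping tally.

Reproducibility takes two disjoint observation windows, restricts to the
cohort of patients with ≥1 ICD-9-CM code in window 1 AND ≥1 ICD-10-CM
code in window 2 (any code — membership is utilization-based, not
phenotype-based), and reports, per target, window-1 cases and the
fraction who are also window-2 cases under the second map, with
`min_code_count` applied per window (default 1).

## PheWAS

Per-phecode binary logistic regression is fitted by maximum likelihood
(statsmodels `Logit`); the exposure is allele dosage (additive 0/1/2 by
default, dominant coding available), with age, a female indicator, and
one-hot race with the largest category as reference. Inference is Wald:
95% CI = exp(β ± 1.96·SE), two-sided p. Perfect or quasi-separation
(detected via statsmodels' error, nonconvergence, or |β| > 15) and
insufficient cases (`min_cases`, default 20 — a common PheWAS floor; the
analysis it emulates states no threshold) flag the phecode untested
rather than imputing an estimate. The Bonferroni threshold is
0.05/(number tested). Excluded patients are dropped from each phecode's
design matrix, and that absence is asserted per fit. Run comparison
inner-joins phecodes tested in both runs and summarizes sign concordance
among doubly Bonferroni-significant hits.

## The synthetic data

The fixture bundle is a miniature terminology: every canonical chain
shape (description match; two-hop GEMS; five-hop concept chain through
two OHDSI concept ids; a parent/child candidate pair; dual-family and
dual-GEMS-target codes; a three-codes-to-one-phecode depression group),
plus decoy codes with no complete chain and deliberately unmapped filler
codes. It exercises every code path of the engine but is four orders of
magnitude smaller than real vocabularies; passing on it demonstrates
correctness of the chain logic and resolution rules, not coverage rates
on real UMLS/GEMS/OHDSI releases, which require licensed downloads.

The cohort simulator draws, per patient: Hardy–Weinberg genotype at a
configurable allele frequency (default 0.066, matching an uncommon risk
variant with ~87/12/0.5% genotype split); age from N(45, 25²) truncated
at 0 by redraw (truncated mean ≈ 46.9); sex 55.1% female; a 70/15/15
race mix. Disease is latent per phenotype: window-1 status from a
prevalence with any planted per-allele effect applied on the log-odds
scale; window-2 status from carry-over (persistence) plus an independent
new-episode risk, so P(case₂ | case₁) = 1 − (1 − persistence)(1 −
incidence) — persistence itself for chronic phenotypes with no new-episode
risk, and exactly the incidence for an acute phenotype with zero
carry-over. Default phenotypes are four chronic diseases with persistence
0.72–0.76 and one acute negative control. Diseased windows emit 1–3 dated
era-appropriate fixture codes; every patient emits one unmapped filler
code per window so two-window cohort membership is universal and
phenotype-independent. Persistence is planted at the phenotype level, not
the code level, because reproducibility is measured at the phenotype
level across coding eras. All output is byte-deterministic given the
seed.

What the simulator does not emulate: realistic code-frequency
distributions, care-setting structure, billing artifacts (rule-out
coding, claim resubmission), informed-presence bias, or correlated
comorbidity — so statistical results on simulated data validate the
estimators, not clinical effect sizes.

## Problem sizes and numerical choices

Test and acceptance workloads use: 20,000 patients for distributional
checks (Hardy–Weinberg within 3 SE; persistence recovery within 1.5
percentage points); 5,000 patients × 100 replicates for Wald CI coverage
of a planted log-OR of log 1.6 (≥ 90/100 expected); 200 replicates of a
100-phecode null phenome at 500 patients for family-wise error control
(observed FWER ≤ 10% against the Bonferroni nominal ~5%); and 1,000
random phecode sets for the hierarchy-resolution oracle comparison.
Percentages are rounded to two decimals at the reporting layer only.
Degenerate inputs are defined, not fatal: empty event tables yield zero
counts with a `no_events` flag, empty bundles yield empty maps, a scan in
which nothing reaches `min_cases` reports an undefined Bonferroni
threshold.

## Known limitations

Sex-specific phecode restrictions are out of scope. The engine maps
forward only (no backward GEMS refinement). The ICD-9-CM phecode map is
consumed as given and never hierarchy-pruned. Manual curation of
mappings, and reproduction of site-specific coverage counts or biobank
odds ratios, are outside what desk-scale synthetic data can support.
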