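# Methods

## Data model and missing-data contract

A cohort is an ordered list of individuals parsed from GA4GH Phenopacket
Schema v2 JSON (supported subset: subject id/sex/last-encounter age/vital
status, phenotypic features with observed/excluded state and onset,
measurements with assay id and unit, diseases with onset, and variant
interpretations). Ages are ISO-8601 durations converted with fixed
constants (month = 1/12 year, day = 1/365.25 year); gestational ages are
rejected. Functional annotation of variants (consequence labels, affected
exons, protein span, change length, structural kind) comes from a sidecar
TSV keyed by variant id, so analyses are hermetic and never call an
annotation service.

Nothing is imputed. A field absent from the input is absent or UNKNOWN in
the model, and every statistic omits individuals whose genotype or
phenotype information is unavailable, reporting `n_used` and `n_omitted`
per hypothesis. Allelic state maps heterozygous/hemizygous → 1 allele and
homozygous → 2; an unparseable state flags the individual genotype-unknown,
and classifiers omit them. More than two annotated alleles in one gene is a
validation error.

## Ontology propagation

The phenotype ontology is a rooted multi-parent DAG over is_a edges
(OBO-graph JSON or a simple edge-list dialect; non-is_a edges dropped with
a warning; cycles rejected). Status resolution for one individual follows
the true path rule: a term is OBSERVED if it lies in the ancestor closure
of any observed feature, else EXCLUDED if it lies in the descendant closure
of any excluded feature, else UNKNOWN. Observation propagates upward only
to (and including) the root of the phenotype domain; terms outside that
subgraph are never tested. When both closures claim a term — contradictory
annotations — the term resolves to UNKNOWN with a logged diagnostic rather
than guessing a precedence. "Depth" for the general-level filter is the
shortest child-edge distance from the root, taking the minimum over
multi-parent paths.

## Statistical engines

**Exact contingency tests.** The 2×2 test computes the hypergeometric
distribution over the table support; the two-sided p-value sums
probabilities of tables whose point probability does not exceed the
observed one, with a relative tie tolerance of 1e-7 (the conventional
"Fisher" two-sided definition; alternatives such as doubling the one-sided
p disagree and are not used). The 3×2 test is the Freeman–Halton
generalization by exhaustive enumeration over margin-consistent tables with
the same ordering rule; rows of zeros are dropped first, so degenerate 3×2
tables reduce exactly to the 2×2 test. Both are checked in the test suite
against exact-rational brute-force enumeration and against an independent
library implementation.

**Multiple-testing correction** delegates to statsmodels and exposes the
eleven classical procedures (Bonferroni, Šidák, Holm, Holm-Šidák, Hommel,
Hochberg/Simes-Hochberg, BH, BY, and the two-stage BH and BKY variants);
Benjamini–Hochberg is the default. Correction is applied within one
categorical run, across the tested terms only. Score, measurement, and
survival runs are treated as distinct hypotheses without correction. The
two-stage adaptive procedures are alpha-specific and may adjust a p-value
below another procedure's output; all others are monotone above the raw p.

**Mann–Whitney U** uses the exact permutation distribution when the
combined sample size is at most 12 and there are no ties, otherwise the
normal approximation with tie and continuity corrections (the approximation
agrees with the exact p to within 0.02 at these sizes). **The t test**
defaults to the pooled-variance statistic with a Welch option; two constant
samples with equal means give p = 1 rather than an error. **The log-rank
test** (2 classes) accumulates observed minus expected events with
hypergeometric variance at each distinct event time; ties use the
simultaneous-event convention and events precede censorings at equal times;
the statistic is referred to chi-square with 1 df. Kaplan–Meier curves come
from lifelines.

Significance is strict: adjusted p < alpha (default 0.05) for categorical
runs, raw p < alpha elsewhere.

## Genotype partitions

Variant predicates are pure boolean functions of one allele's annotation;
region predicates use any-overlap with 1-based inclusive coordinates; the
structural predicate accepts an event whose kind matches when it is either
sequence-resolved with |change length| ≥ 50 bp (configurable) or imprecise
(no coordinates). Mono- and bi-allelic classifiers count only alleles
matching A ∪ B: mono-allelic assigns individuals whose qualifying-allele
total is exactly one (omitting non-carriers, homozygotes and compound
heterozygotes), bi-allelic assigns individuals with exactly two qualifying
alleles by their A-allele count, optionally merging AA/AB against BB. When
an allele satisfies both predicates, A takes precedence. An individual
carrying both diagnoses under the diagnosis classifier is omitted — there
is no principled tie-break. Swapping the two predicates provably swaps the
class labels and nothing else.

## Phenotype severity scores

The counting scorer takes a list of component terms and adds one point per
component with at least one observed annotation in its descendant closure;
multiple hits per component still score one. The de Vries score is adapted
to HPO with a declared, editable anchor table: D1 developmental
delay/intellectual disability (2 points for a severe/profound subtype, else
1); D2 prenatal-onset growth retardation (2); D3 postnatal growth
abnormalities (1 each for short/tall stature and micro-/macrocephaly,
capped at 2); D4 at least two distinct facial dysmorphism annotations (2);
D5 non-facial dysmorphisms and congenital anomalies (1 each, capped at 2);
maximum 10. The component point values are this package's declared
configuration, chosen for reproducibility — published variants of the
score differ in details, and no claim is made about any other
implementation. An individual with no known annotation touching any
component is excluded (NaN) rather than scored zero, mirroring the
missing-data contract; a counting score with no relevant annotations is a
true zero.

## Survival endpoints

Term-onset endpoints roll annotations up the ontology: the event time is
the youngest onset among observed features in the endpoint term's
descendant closure. Individuals without the event are censored at the age
of last encounter; individuals with an undated event, or with neither an
event age nor a censoring age, are omitted and counted. Death uses the age
at death (alive individuals censored at last encounter; unknown vital
status omitted); disease onset uses the disease element's onset, censoring
individuals without the diagnosis at last encounter. Zero-time (congenital)
events are allowed.

## Synthetic-data generator

The generator emulates the *structure* of curated case-report cohorts: a
rooted DAG with configurable branches, depth, fanout and multi-parent
fraction; individuals with a genotype class drawn from a configurable split
(or balanced exactly); leaf-level annotations drawn per-class from planted
penetrances; explicit exclusions recorded with probability 0.5 when a
feature is absent (case reports record some but not all negatives); a 10%
chance any feature's status goes unrecorded; onsets from per-class
exponential or Weibull distributions with independent uniform censoring;
and per-class Gaussian measurements. Nuisance (null) leaves draw one
class-independent penetrance each from Uniform(0.05, 0.35), the range of
uncommon-to-moderate feature frequencies typical of such cohorts. Causal
variants are fabricated so the shipped classifier reproduces the planted
classes exactly, and phenopackets/sidecar/ontology/truth are written as
deterministic, byte-identical files per seed.

What the generator does **not** emulate: real HPO term-frequency profiles,
correlated feature co-occurrence beyond shared ancestry, curation noise
(typos, obsolete terms), age-dependent penetrance, or realistic variant
spectra. Passing simulations therefore demonstrate correctness of the
machinery and its operating characteristics under idealized annotation
practice, not performance on any real cohort.

## Simulation study sizes

The property suites use: 2,000 replicates (n = 50, 100 nuisance terms) for
null family-wise error control of the filtered categorical pipeline; 200
replicates (n = 25/25, planted penetrance 0.8 vs 0.2, 300 nuisance terms)
for the filtering-vs-test-all power comparison; 200 replicates each for
log-rank power (exponential onsets at rate 2 vs 0.5 per year, n = 50/50,
30% censoring) and t-test power (one-SD shift, n = 40/40). The acceptance
script reruns the simulation estimates at 500/100/100 replicates, sizes
chosen to keep a full reproduction run under a minute on one CPU while
leaving Monte Carlo error well inside the asserted margins.

## Design choices on open points

- The general-level skip depth is configurable because the two natural
  readings (skip two levels below the root vs three) both occur in
  practice; the default is 3 (root's children and grandchildren are all
  group terms).
- The coverage rule's denominator defaults to the full classified cohort,
  with a `known`-only option.
- The 3×2 low-total threshold of 6 is implemented as specified even though
  enumeration shows no 3×2 table with 6 individuals reaches two-sided
  p < 0.05 (the minimum is ≈ 0.067); the filter is deliberately not
  second-guessed.
- Filter rules are applied in a fixed order (general level, same-as-child,
  coverage, total, empty class) with first-match-wins reporting; since each
  rule is an independent criterion, order affects only the reported reason,
  never the tested set.
- Homozygous carriers of an A-matching allele are never admitted to
  mono-allelic analyses under any configuration.

## Known limitations

- The log-rank test is limited to two classes; no Cox regression, interval
  censoring, or left truncation.
- No mid-p or unconditional (Barnard/Boschloo) exact tests.
- r×2 exact tests support at most three non-empty rows.
- Ontology handling covers is_a reasoning only: no obsolete-term
  replacement, no non-is_a relations, no reasoning outside the phenotype
  root's subgraph.
- The protein lollipop view skips non-coding and structural variants (they
  are counted in the legend) and relies on a locally supplied domain table.
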