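# phenogpc

Genotype–phenotype correlation (GPC) analysis for cohorts of GA4GH
phenopacket-style case records.

## The problem

In Mendelian disease, carriers of different variant classes in the same gene
often differ in which clinical features they show, how severe those features
are, and when they appear. Detecting such correlations from published case
reports requires (a) a case-level data model rich enough to hold observed
*and* explicitly excluded phenotype terms, onsets, measurements, and causal
variants; (b) ontology-aware counting, because Human Phenotype Ontology
(HPO) annotations obey the *true path rule* — an annotation to *Nuclear
cataract* entails *Cataract* and every other ancestor, while exclusion of
*Cataract* entails exclusion of every descendant; and (c) careful control of
the multiple-testing burden when hundreds of HPO terms are candidates.

`phenogpc` is a toolkit for exactly this workflow, aimed at clinical
geneticists and methodologists analyzing curated phenopacket cohorts:

1. **Load** a directory of phenopacket JSON files plus a variant
   functional-annotation sidecar TSV (consequence, exon, protein span,
   change length) into a validated in-memory cohort. Missing data are never
   imputed; statistics omit individuals whose genotype or phenotype status
   is unknown.
2. **Partition** the cohort by genotype with composable variant predicates
   (consequence, exon, protein region, change length, structural kind,
   combined with AND/OR/NOT) feeding five classifiers: mono-allelic,
   bi-allelic (AA/AB/BB or a two-way merge), allele count, sex, and
   diagnosis.
3. **Test** four kinds of clinical data:
   - categorical HPO terms — Fisher's exact test on the 2×2 table of
     genotype class × observed/excluded status (Freeman–Halton exact test
     for 3-class partitions), with independent filtering (below) and
     Benjamini–Hochberg correction across the tested terms;
   - phenotype severity scores (counting scorer, HPO-adapted de Vries
     score, or user-supplied) — Mann–Whitney U;
   - numerical measurements (e.g. LOINC-coded assays) — unpaired two-sided
     *t* test;
   - time-to-event endpoints (disease onset, HPO-term onset with roll-up to
     the youngest descendant onset, death) — Kaplan–Meier curves and the
     log-rank test with right censoring at the last encounter.

## Independent filtering (IF-HPO)

Testing every annotated term wastes power: most tests are redundant or
hopeless. Before any test is run, terms are filtered by five rules that
depend only on ontology structure and table margins — quantities
independent of the test statistic under the null, so type-I error control
is preserved (the strategy familiar from independent filtering in
high-dimensional genomics). A term is skipped when it is

1. *general-level*: within `general_depth` (default 3) child-edges of the
   *Phenotypic abnormality* root, or outside the root's subgraph;
2. *same as a child*: its per-class (observed, known) counts are identical
   to a child term's, so its annotations derive entirely from the child;
3. *low coverage*: observed in less than `min_coverage_fraction` (default
   0.4) of the classified cohort;
4. *low total*: fewer than 7 informative individuals for a 2×2 table
   (6 for 3×2) — by exhaustive enumeration, no 2×2 table with fewer than 7
   individuals can reach two-sided p < 0.05;
5. *empty class*: some genotype class has neither an observed nor an
   excluded status for the term.

Every skipped term is reported with its rule in a companion skip table.

## Worked example

The synthetic-data module generates hermetic fixtures: a toy ontology and a
phenopacket cohort with a planted genotype–phenotype effect.

```python
from phenogpc.simulate import make_toy_ontology, SimConfig, simulate_cohort, planted_classifier
from phenogpc import engine

graph = make_toy_ontology(branches=3, depth=4, fanout=2, seed=1)
leaves = sorted(t for t in graph.phenotype_domain if not graph.children(t))
config = SimConfig(seed=11, n_individuals=40,
                   penetrance={leaves[0]: (0.9, 0.1)},   # planted effect
                   n_nuisance_terms=8, balanced_classes=True)
cohort, truth = simulate_cohort(graph, config)
result = engine.run_categorical(cohort, planted_classifier(), graph)
print(result.table[["term_id", "counts", "p_raw", "p_adjusted", "significant"]].to_string(index=False))
```

prints

```
   term_id                      counts    p_raw  p_adjusted  significant
HP:5000008 class0: 16/16; class1: 1/10 0.000003    0.000003         True
```

The planted leaf term was observed in 16 of 16 status-known individuals
carrying the class-0 (missense) allele and 1 of 10 carrying the class-1
(stop-gained) allele; Fisher's exact test gives p = 3 × 10⁻⁶, and since
filtering left a single testable term, the adjusted p is unchanged. The
companion skip report accounts for every untested term (here 14
general-level and 8 low-coverage terms).

The same pipeline is available from the shell:

```bash
phenogpc simulate --seed 5 --out fixture/
phenogpc categorical --cohort fixture/phenopackets --ontology fixture/ontology.json \
    --annotations fixture/annotations.tsv --classifier classifier.json --out results/
```

where `classifier.json` holds a small JSON grammar, e.g.
`{"type": "monoallelic", "a": {"consequence": "missense_variant"}}`.

## Documentation

See `docs/methods.md` for the statistical model, propagation semantics,
default parameters, what the synthetic-data generator does and does not
emulate, and known limitations.
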