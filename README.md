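# cpgselect

Two-stage CpG-site selection for human age prediction from DNA-methylation
beta values.

**Stage 1 — age grouping.** Samples are binned into decade classes
(0–103 years), a linear SVM on 60 PCA components predicts the class, and
classes the classifier confuses are merged (adjacent classes only, so
groups remain age intervals) down to a target number of age groups. The
fixed 5-group and 3-group schemes — `(1)(2,3)(4,5)(6,7)(8–10)` and
`(1,2)(3,4,5)(6–10)`, i.e. age intervals `[0,20) [20,50) [50,103]` — are
built in; an automated confusion-driven merge is also provided. Test
samples are routed to groups by the classifier's *predicted* label.

**Stage 2 — per-group site selection.** Within each group's training data,
CpGs are pre-filtered to the top-k (default 8000) by |Pearson r| with age,
then a genetic algorithm searches binary site masks. A chromosome's fitness
is the cross-validated MAD of a gradient-boosted regressor (LAD loss,
300 trees), averaged over ~100-sample partitions, plus one penalty unit per
50 selected sites. Operators: roulette-wheel selection with inverse-fitness
weights, agreement-preserving crossover (the second child complements the
first at every disagreeing locus), balanced k-gene mutation, and top-10
elitism. Fitness evaluation follows a map/reduce contract — each
(chromosome, partition) work unit is independently seeded, so results are
bit-identical at any parallelism degree. The winning panel is finally
ranked by stepwise forward selection with backward elimination.

A synthetic-cohort generator (`cpgselect.synth`) plants age-informative
CpGs with continuous piecewise-linear drift, regime-specific noise,
missingness, and outlier samples, so the whole pipeline is testable without
external data.

## CLI

```sh
cpgselect simulate --n-samples 300 --n-sites 1000 --n-informative 20 \
    --seed 1 --out cohort.csv
cpgselect preprocess --in cohort.csv --out train.csv --test-out test.csv
cpgselect group confusion --train train.csv --scheme identity --out confusion.csv
cpgselect group assign --train train.csv --test test.csv --out groups.tsv
cpgselect filter --in train.csv --k 8000 --out ranking.tsv
cpgselect ga --in filtered.csv --population 100 --generations 100 \
    --out sites.txt --history-out history.csv
cpgselect sfs --in train.csv --sites sites.txt --out report.tsv
cpgselect run-all --config pipeline.yaml --outdir results/
```

`run-all` drives the whole chain from a YAML config whose sections mirror
the parameter dataclasses (`synth`, `ga`, `gbr`, `sfs` plus top-level
keys such as `scheme`, `filter_k`, `parallelism_degree`, `seed`); see
`tests/test_pipeline.py` for a working example. Every artifact is stamped
with the config hash and master seed; a rerun with the same config is
bit-identical at any parallelism degree.

Data formats are plain text: delimited beta matrices (header = site ids,
reserved `age` column) and the GEO series-matrix dialect
(`cpgselect.data.read_geo_series_matrix`, with a configurable
characteristics field for the age).

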