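# irdl

Associating divergent lncRNAs with the protein-coding genes they regulate in
cis, by iterative self-training on genomic co-variation features.

Divergent lncRNAs are transcribed head-to-head with a nearby protein-coding
gene, and a subset of them positively regulate that gene. Experimentally
validated regulatory pairs are scarce (a handful of knockdown-confirmed
cases), while thousands of divergent pairs are plausible candidates. `irdl`
treats this as a positive-unlabeled learning problem for researchers in
regulatory genomics who have paired cross-sample expression (RNA-seq) and
chromatin-accessibility (DNase/ATAC-seq) panels and want a ranked,
tissue-annotated list of candidate regulatory pairs.

## The model

Each lncRNA-gene pair is summarised by four features:

- **sequence correlation** — Pearson correlation of the members' k-mer
  frequency vectors (k = 1..3 concatenated; 4 + 16 + 64 = 84 dimensions);
- **expression correlation** — Pearson correlation of log2 expression
  profiles across samples;
- **openness correlation** — Pearson correlation of chromatin-accessibility
  profiles, where the openness of a region is the pseudocount-stabilised
  fold change of reads per base pair over a background region,
  O = ((X+δ)/L) / ((Y+δ)/L₀), δ = 5;
- **genome distance** — log10(|gene TSS − lncRNA TSS| + 1), with
  cross-chromosome pairs at a chromosome-scale cap.

Starting from the validated positives, each iteration (i) resamples
negatives from a pool of nearby lncRNA-gene pairs at a 1:5
positive:negative ratio, (ii) fits an RBF-kernel SVM with C and gamma chosen
by stratified 3-fold cross-validation maximising AUPR and with
Platt-calibrated probability output, and (iii) promotes every remaining
candidate whose predicted probability exceeds 0.9 into the positive set.
The loop stops once at most one new positive is admitted in two consecutive
iterations. Identified associations are then assigned a specific tissue/cell
type by the enrichment score ES = (m·n)/(p·q) over each pair's
high-expression samples, and a per-gene random-forest regression baseline is
provided for comparison.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic panel (56 samples, 8 seed positives, 20 planted
regulatory pairs among 220 candidates) and run the self-training loop:

```python
from irdl.features import log2_transform
from irdl.learner import LearnerConfig, run_increasing_learning
from irdl.pipeline import compute_feature_table
from irdl.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(seed=7))
table = compute_feature_table(
    ds.pairs, {f.id: f for f in ds.features}, ds.sequences,
    log2_transform(ds.gene_expr_raw), log2_transform(ds.lnc_expr_raw),
    ds.gene_open, ds.lnc_open,
)
positives = [p for p in ds.pairs if p.role == "positive"]
pool = [p for p in ds.pairs if p.role == "nearby_pool"]
candidates = [p for p in ds.pairs if p.role == "candidate"]
identified, state = run_increasing_learning(
    positives, pool, candidates, table, LearnerConfig(), master_seed=7
)
print(f"identified {len(identified)} associations in {len(state.iteration_log)} iterations")
for rec in state.iteration_log:
    print(f"  iter {rec.iteration}: {rec.n_positives_before} positives, "
          f"+{rec.n_added} admitted (C={rec.C:g}, gamma={rec.gamma:g}, cv AUPR={rec.cv_aupr:.3f})")
```

prints

```
identified 20 associations in 3 iterations
  iter 1: 8 positives, +20 admitted (C=0.125, gamma=0.0078125, cv AUPR=1.000)
  iter 2: 28 positives, +0 admitted (C=0.125, gamma=0.0078125, cv AUPR=1.000)
  iter 3: 28 positives, +0 admitted (C=0.125, gamma=0.0078125, cv AUPR=1.000)
```

All 20 planted pairs were promoted in the first round (their expression and
openness correlations sit near 0.9 while decoys sit near 0), and the loop
then observed two consecutive zero-admission rounds and stopped. Checked
against the planted truth this run has precision 1.00 and recall 1.00, and
`summarize_pair_properties` reports all 20 identified pairs within 100 kb
and with expression/openness correlation above 0.7 — the genomic profile the
method selects for.

The same pipeline is available from the shell:

```sh
irdl simulate --seed 7 --out fixtures/
irdl run --config run.yaml --seed 7 --out results/   # paths to the fixtures
irdl tissues --associations results/identified_associations.tsv \
     --gene-expr fixtures/gene_expression.tsv --lnc-expr fixtures/lncrna_expression.tsv \
     --sample-tissues samples.tsv --out tissues.tsv
```

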