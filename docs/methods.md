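# Methods

## Problem and model

Divergent lncRNAs sit head-to-head with a protein-coding gene, transcribed in
the opposite direction from a shared intergenic region, and a subset of them
positively regulate that gene in cis. Experimentally validated examples are
rare — the training signal here is eight knockdown-validated pairs — while
thousands of divergent pairs are candidates. The package treats the problem
as positive-unlabeled learning and grows the positive set by self-training
("increasingly learning"):

1. **Features.** Each lncRNA-gene pair is a 4-vector:
   - `seq_pcc`: Pearson correlation of the two members' k-mer frequency
     vectors (k = 1..3 concatenated: 4 + 16 + 64 = 84 dimensions,
     lexicographic within each block; windows containing non-ACGT letters are
     excluded from numerator and denominator).
   - `expr_pcc`: Pearson correlation of log2-transformed expression profiles
     across the sample panel.
   - `open_pcc`: Pearson correlation of chromatin-accessibility (openness)
     profiles. Openness of a region is the pseudocount-stabilised fold change
     of reads per base pair against a background region,
     O = ((X+δ)/L) / ((Y+δ)/L₀), with δ = 5 by default.
   - `distance_feature`: log10(|d|+1) of the signed genome distance
     (gene TSS − lncRNA TSS); cross-chromosome pairs saturate at a
     chromosome-scale cap of 2.5×10⁸ bp. The distance itself is carried as a
     dedicated infinity sentinel and only bounded at encoding time.
2. **Classifier.** An RBF-kernel SVM. Features are z-scored with training
   statistics recomputed each iteration (stored in the fitted pipeline). The
   penalty C and kernel width gamma are grid-searched
   (C ∈ {2⁻³, 2⁻¹, …, 2⁷}, gamma ∈ {2⁻⁷, …, 2¹}) by stratified 3-fold
   cross-validation maximising AUPR on held-out decision values; ties go to
   the smallest C, then the smallest gamma. The final model is refit on all
   data with Platt-style sigmoid calibration on cross-validated decision
   values, so the admission threshold applies to a probability.
3. **Self-training loop.** Each iteration resamples fresh negatives from the
   nearby-pair pool at 5× the *current* positive count (previous negatives
   are discarded), refits, scores the remaining candidates, and promotes
   every candidate with probability > 0.9. Promoted pairs leave the scoring
   pool and are never used as negatives. The loop stops when at most one new
   positive is admitted in each of two consecutive iterations (the ≤ 1
   reading is the default because it is the only one under which
   zero-admission runs terminate; a strict == 1 reading is available via
   `strict_stopping`), or at the `max_iterations = 50` safeguard.
4. **Evaluation.** AUPR (average precision: descending-score threshold sweep
   with tied scores as one block), the appropriate index at a 1:5 class
   imbalance.

Per-iteration randomness derives deterministically from one master seed via
`numpy.random.SeedSequence((master_seed, iteration))`, so a run is exactly
reproducible from its config and seed.

## Tissue/cell specificity

For each identified association, the samples where the gene exceeds 6 and
the lncRNA exceeds 4 (strict inequality) are collected; for every tissue
present in both high-expression sets the enrichment score
ES = (m·n)/(p·q) is computed from the within-tissue counts (m, n) and totals
(p, q), and the pair is assigned the argmax tissue. Ties are all reported
with the lexicographically smallest as primary; pairs with empty overlap or
no high-expression samples get no assignment. The thresholds are applied on
whatever scale the matrices are loaded in; the CLI warns when they are
applied to raw counts, since such cutoffs are ordinarily meant for log-scale
values.

## Random-forest baseline

The comparison route regresses one gene's expression on candidate lncRNAs'
expression with a 500-tree random forest and ranks regulators by
impurity-based importance (permutation importance optional). No importance
cutoff is imposed; the full ranking is reported.

## Synthetic data: what it emulates and what it does not

The generator emulates a 56-sample paired expression/accessibility panel
(the size of the mouse cell-line panel this method targets) with 8 seed
positives, 20 planted candidate positives, 200 decoy candidates and a
300-pair nearby pool. Planted pairs get head-to-head geometry with TSS gaps
drawn from 500–10 000 bp and expression/openness profiles drawn as bivariate
normals with target correlation 0.9 (Cholesky construction), exponentiated
to non-negative raw expression so the log2 path is exercised. Openness is
generated as integer read counts (region length 1 000 bp, background
10 000 bp, δ = 5) and the precomputed matrices are derived from those very
tables, so the two representations agree exactly. Sequences are i.i.d.
uniform ACGT and unrelated within a pair: planted pairs are detectable
through co-expression and co-accessibility, not sequence, mirroring the
genomic profile of the validated pairs. Decoys have independent profiles and
arbitrary distances, a fifth of them cross-chromosome.

What it does **not** model: real read-depth and GC structure, correlated
backgrounds between samples, batch effects, partially correlated decoys, or
annotation errors. Passing the recovery tests therefore shows the algorithm
and its contracts are implemented correctly and can separate a clean planted
signal; it does not certify real-data performance, where candidate pairs are
far noisier and the positive signal weaker.

## Numerical choices and degenerate inputs

- Zero-variance profiles give an undefined Pearson correlation; it is
  encoded as 0 (neutral) with a logged warning so the feature matrix stays
  finite.
- `openness_score` with δ = 0 and Y = 0 raises a division error naming the
  input; the default δ = 5 makes the score strictly positive.
- A k-mer block with no valid window (sequence shorter than k, or all
  ambiguous) is all zeros with a warning.
- All-identical feature rows train a constant scorer whose CV AUPR equals
  the positive prevalence (1/6 at the 1:5 ratio) — documented degenerate
  output, not an error.
- TSS is strand-aware by default (start on +, end on −); a `raw_start` mode
  exists for annotations whose start column is already the TSS.
- Problem sizes in the test suite and acceptance script (scaled-down runs
  for structural checks, five master seeds at full default conditions for
  recovery) are the package's chosen desk-scale study conditions.

## Known limitations

- The self-training loop refits from scratch each iteration; no warm starts.
- Negatives are resampled fresh each round; a cumulative-negative variant is
  not implemented.
- The sequence feature defaults to the annotated body; a fixed-width
  promoter mode is a config option but no claim is made about which a given
  annotation set should use.
- Specificity thresholds (6/4) are scale-dependent and left to the caller's
  declaration of the expression space.
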