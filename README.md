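# tspred

Structure-informed prediction of temperature-sensitive (ts) point mutations.

Temperature-sensitive alleles — substitutions that leave a protein functional
at a permissive temperature but inactivate it at a restrictive one — are a
workhorse for studying essential genes, and they are expensive to find by
random mutagenesis.  `tspred` ranks candidate substitutions at buried sites
of a protein by how likely they are to produce a ts phenotype, on the premise
that ts mutations occupy an intermediate window of destabilization between
tolerated and outright loss-of-function changes.

The pipeline:

1. **Site selection.**  Positions with relative side-chain solvent
   accessibility ≤ 10 % are selected, and all 19 substitutions are
   enumerated at each.  A run manifest is emitted with one structure-relax
   job for the wild type and one per mutation (4 buried sites → 77 jobs).
2. **Ensemble comparison.**  Each relax job produces an ensemble of 50
   low-energy conformations with 31 score terms per decoy.  For every term,
   the mutant ensemble's quartiles Q1–Q3 are expressed as percentile
   fractions within the wild-type ensemble's empirical distribution of the
   same term (clamped to [0, 1]), giving 93 distribution-free features per
   mutation:

   `{term}Qk = F̂_wt( Q_k(mutant term values) )`,  k ∈ {1, 2, 3}

3. **Auxiliary features.**  Amino-acid category-change codes under a 4-class
   and a 7-class partition, PSI-BLAST PSSM log-odds/frequency/information
   features, percent accessibility, and secondary-structure indicators.
   Redundant features are pruned group-wise by score term.
4. **Classification.**  Soft-margin SVMs — `SVM-LIN` (linear kernel,
   interpretable weights), `SVM-RBF` (radial basis kernel, non-linear
   boundaries around the intermediate band), and `SVM-seq` (RBF on sequence
   features only).  Labels follow the sign of
   `f(x) = Σᵢ αᵢ yᵢ K(xᵢ, x) + b`; margins are mapped to confidences by a
   slope-only Platt sigmoid, and candidates are emitted as a
   confidence-ranked list.
5. **Validation.**  Stratified 10×10-fold CV and nested 5× leave-out CV with
   (C, γ) grid search in log space; metrics are ts-class precision, AUROC
   (tie-aware Mann–Whitney rank statistic), AUPR, and the point-biserial
   correlation between confidence and correctness.

A synthetic-data module emulates every upstream input (score ensembles with
a planted intermediate-destabilization labelling rule, PSSMs, accessibility
tables), so the entire pipeline downstream of the external structure runs is
testable offline.

## Worked example

Materialize a toy workspace (synthetic protein, score ensembles, PSSM,
training matrix, trained models), then rank its candidate mutations:

```sh
tspred fixtures --out demo --seed 4 --n-ts 12 --n-nonts 18 --ensemble-size 20
tspred predict --protein TOY1 --species Synt --workspace demo \
    --model-lin demo/models/svmlin.json --model-rbf demo/models/svmrbf.json \
    --out-dir demo/preds
head -6 demo/preds/TOY1-svmrbf.txt
```

prints

```
rank conf id
1  0.999 TOY1-Y7_PRO_Synt
2  0.998 TOY1-M4_HIS_Synt
3  0.998 TOY1-M4_GLU_Synt
4  0.997 TOY1-Y7_ARG_Synt
5  0.995 TOY1-M4_GLY_Synt
```

Each line gives the absolute rank, the calibrated probability that the
substitution is temperature-sensitive, and the mutation id
(`{protein}-{native}{position}_{mutant three-letter code}_{species}`).
Here the toy protein's two buried sites (M4, Y7) contribute 38 candidates;
proline and glycine substitutions in the hydrophobic core rank near the top,
as expected for destabilizing-but-not-lethal changes.

For a real protein the workflow is the same, except that `tspred generate`
writes the relax/rescore job manifest, the jobs are executed externally
(typically on a cluster), and `tspred predict` consumes their score files.
`tspred train` and `tspred evaluate` fit and cross-validate classifiers on a
labelled feature matrix.

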