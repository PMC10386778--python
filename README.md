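# stacktide

Stacked ensemble learning for predicting **tumor T-cell antigens (TTCAs)**
from peptide sequence alone.

TTCAs are short tumor-derived peptides, presented on MHC class I, that can
elicit a cytotoxic T-cell response — prime candidates for cancer vaccine
design. Screening candidates experimentally is slow, so sequence-based
classifiers are used to triage peptide libraries. `stacktide` implements a
three-stage stacking architecture for this problem:

1. **Baseline grid.** Each peptide is described by 12 feature encodings
   (amino acid and dipeptide composition, composition/transition/distribution
   descriptors, pseudo and amphiphilic pseudo amino acid composition,
   physicochemical property means, and five reduced-alphabet n-gram schemes).
   13 machine-learning algorithms (AdaBoost, decision tree, extra trees,
   k-NN, LightGBM, logistic regression, MLP, naive Bayes, PLS, random
   forest, linear and RBF SVM, XGBoost) are trained on each encoding,
   giving 13 × 12 = **156 baseline classifiers**.
2. **Probabilistic meta-features.** Under one shared stratified 10-fold
   partition, every baseline produces a strictly out-of-fold probability for
   every training peptide. Stacking them column-wise yields the
   156-dimensional probabilistic feature vector

   `APF = {PF_1,1, PF_1,2, …, PF_i,j, …, PF_13,12}`,

   where `PF_i,j` is the positive-class probability from algorithm *i* on
   encoding *j*.
3. **Selection + meta-classifier.** A genetic algorithm with binary genes
   (one per probability column) and one parametric gene (the tree count of
   an extremely-randomized-trees meta-classifier, from {20, 50, 100, 200,
   500}) maximizes cross-validated MCC (population 20, 20 generations,
   mutation probability 0.05, 5 initial active genes, at most 20 active
   genes). The meta-classifier trained on the selected columns (the *BPF*)
   is the final predictor.

Evaluation uses ACC, sensitivity (Sn), specificity (Sp), the Matthews
correlation coefficient

`MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`,

and the rank-statistic AUC. Average-score and majority-vote ensembles over
the same 156 probability columns are provided as comparison strategies.

A synthetic peptide generator (class-dependent residue composition bias,
lengths 8–30) makes every stage testable without external data.

## Worked example

```sh
stacktide simulate --n-pos 200 --n-neg 200 --effect strong --seed 7 \
    --fasta-out train.fa --table-out train.tsv
stacktide train --table train.tsv --seed 7 \
    --algorithms ET,LR,XGB,NB --generations 6 --pop-size 10 \
    --model-out model.joblib --report-out report.json
```

The train command prints the pooled cross-validation report of the final
stacked model, e.g.:

```json
{
  "TP": 185, "TN": 176, "FP": 24, "FN": 15,
  "ACC": 0.9025, "Sn": 0.925, "Sp": 0.88,
  "MCC": 0.805816302468796, "AUC": 0.9488125,
  "context": "cross_validation"
}
```

read as: of 400 synthetic peptides, 361 were classified correctly
out-of-fold (ACC 0.9025), with sensitivity 0.925 and specificity 0.88, and
an MCC of 0.81; the AUC of 0.949 means a random positive outscores a random
negative 94.9% of the time. `report.json` additionally records the selected
probability columns (in this run 20 of 48, among them `"XGB-CTD"` and
`"LR-PAAC"`), the chosen meta-classifier tree count (50), and the
per-generation GA fitness history. Predict and evaluate with:

```sh
stacktide predict --model model.joblib candidates.fa --out predictions.csv
stacktide evaluate --model model.joblib --table held_out.tsv
```

Python API: `stacktide.pipeline.train_pipeline` runs the same stages
programmatically; `encoder_registry()`, `algorithm_registry()`,
`build_apf_train`, `run_ga`, `fit_stack` expose the pieces.

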