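# stabnet

Hybrid Bayesian-network modelling of metabolic protein stability.

Proteins turn over at very different rates, and the determinants of that
turnover — N-terminal degrons, post-translational modifications, domain
content, structural disorder, amino-acid composition — are scattered
across heterogeneous data sources. `stabnet` is a toolkit for researchers
who want to (1) derive stable/unstable protein classes from 7-bin FACS
stability profiles (global protein stability profiling), (2) test which
features are enriched in each class, and (3) train and evaluate a
classifier that integrates all of the evidence, including sources that
are missing for many proteins.

## The model

Stability classes come from complete-linkage hierarchical clustering of
the normalized bin distributions; the bin-weighted mean
`PSI = Σ_i R_i·i ∈ [1,7]` summarizes each profile. Class prediction uses
a hybrid Bayesian network whose joint factorizes as
`P(X_1..X_N) = Π_i P(X_i | pa(X_i))` over 20 Boolean nodes and 3
continuous leaves:

* a **Stability** node conditioned on N-terminal degron status and three
  latent aggregators — **PTM** (leaky noisy-OR of 4 modification flags,
  `P(on | S) = 1 − (1−c0)Π_{i∈S} q_i`), **Domain** (noisy-OR of 9
  domain/architecture flags) and **Disorder** (table over 2 high-disorder
  indicators);
* Gaussian density leaves carrying a **1-spectrum-kernel SVM** score
  (amino-acid composition; child of Stability) and two **phosphosite PWM**
  maxima (cells `log((F + BG/10)/BG)`; children of the phosphorylation
  flags).

Parameters are learned by EM with exact inference over the latent and
unknown nodes, Laplace-smoothed tables and a numerically maximized
noisy-OR M-step; variants with the sequence leaf removed (BN) or only the
sequence leaf kept (SVM) support ablation. Evaluation is repeated
stratified cross-validation with AUC, and F/MCC/sensitivity/specificity
at the maximum-F threshold. A synthetic-fixture generator produces every
input the pipeline consumes — bin tables, annotations, sequences, motif
windows — with planted ground truth, so the whole stack is testable
offline. See `docs/methods.md` for the full model description.

## A worked example

```bash
python examples/classify_stability_groups.py
```

```
200 proteins clustered into 3 groups

       unstable: n =  40   mean PSI = 2.35
   non_assigned: n = 120   mean PSI = 3.58
         stable: n =  40   mean PSI = 5.33

agreement with the planted grouping: 200/200
```

The three groups separate cleanly and mean PSI rises from the unstable
class to the stable one, as it must: PSI weights the late (stable) bins
more heavily. Comparing the model variants by cross-validation
(`python examples/cross_validation.py`, 310 proteins, 5-fold × 2):

```
   model            AUC              F            MCC
     svm    0.977±0.001    0.945±0.004    0.894±0.010
      bn    0.696±0.016    0.710±0.016    0.341±0.052
  bn_svm    0.983±0.000    0.949±0.002    0.900±0.003
```

On this benchmark the sequence signal is strong, the annotation-only
network is informative but weaker, and the hybrid matches or beats both —
the integration never costs accuracy. `examples/train_and_predict.py`
shows proteome-style classification with the (0.2, 0.75) thresholds, and
`examples/feature_enrichment.py` the Fisher-exact enrichment screen.

The same capabilities are available from the shell:

```bash
stabnet simulate --seed 0 --out-dir bench/
stabnet cluster --gpsp bench/gpsp.tsv --k 3 --out labels.tsv
stabnet evaluate --fasta bench/seqs.fa --annot bench/annot.tsv \
    --labels bench/labels.tsv --motifs bench/motifs.json \
    --variant bn_svm --folds 10 --repeats 5 --seed 0 --out report.json
```

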