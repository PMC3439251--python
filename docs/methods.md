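# Methods

## Problem setting

Global protein-stability profiling reads a protein's metabolic stability
out by FACS: cells expressing an EGFP-fusion of the protein are sorted
into seven sub-populations (bins R1–R7) by increasing EGFP/DsRed ratio,
and the normalized distribution of cells across the bins summarizes the
fusion's turnover. `stabnet` models the mapping from sequence- and
annotation-derived protein features to a stable/unstable classification
derived from such 7-bin profiles.

## Stability classes

The bin-weighted mean, the protein stability index

    PSI = Σ_{i=1..7} R_i · i,     PSI ∈ [1, 7],

is a continuous stability surrogate, but thresholding it directly is
arbitrary. Classes are instead derived from the geometry of the bin
distributions: complete-linkage agglomerative clustering under Euclidean
distance (`scipy.cluster.hierarchy.linkage`), the tree cut into `k = 3`
groups. The group whose centroid carries the most mass in R1+R2 is
labelled *unstable*, the one with the most mass in R5+R6+R7 *stable*, and
everything else *non-assigned*. The linkage criterion and the cut are not
uniquely dictated by the clustering idea itself; complete linkage is the
classical default of the standard hierarchical-clustering routine, and
both linkage and `k` are exposed as configuration. The centroid-mass rule
replaces a by-eye reading of the clustered heat-map with a deterministic
criterion; it errs if one group maximizes both extreme masses, since such
data have no stable/unstable dichotomy at that cut.

## Features

Each protein is described by 19 components:

* **N-terminal degron status** (1). The mature N-terminus is the residue
  after the signal-peptide cleavage site when one is annotated (1-based
  position of the last signal residue; mature chain starts one later);
  otherwise the initiator Met is removed when the second residue is one
  of C, G, A, S, T, V, P, exposing it. The exposed residue is
  *destabilizing* iff it is one of R, K, H, F, L, W, I, Y (the original
  N-end rule's destabilizing set; the acetylation-dependent extension is
  deliberately not encoded). Non-standard residues give an *unknown*
  state rather than an error.
* **4 PTM flags** (tyrosine phosphorylation, Ser/Thr phosphorylation,
  acetylation, glycosylation), tri-state: absent annotation loads as
  *unknown*, not false — non-annotation in a curated database is not
  evidence of absence, and the network can marginalize over unknowns.
* **9 domain/architecture flags** (transmembrane, signal peptide,
  loops/coils motif, three immunoglobulin families, zinc-finger-C2,
  cadherin, RNA-recognition motif), strict Booleans.
* **2 high-disorder indicators**: the fraction of the sequence predicted
  disordered (loops/coils and hot-loops definitions) binned into five
  20%-wide levels — level 1 is the closed band [0, 0.2], levels 2–5 the
  half-open bands (0.2, 0.4] … (0.8, 1.0] — with the indicator true iff
  the fraction falls in the 80–100% band. The statistical layer tests all
  15 type × level indicators; the network consumes only the two
  80–100% flags.
* **2 phosphosite PWM scores and 1 sequence-SVM score**, described below.

## Enrichment statistics

Per feature and stability class, a 2×2 table (class membership ×
feature presence) is tested with a two-sided Fisher exact test; the
direction is read off the sample odds ratio. One two-sided test per
feature avoids doubling the test count relative to separate one-sided
over/under tests. Reported E-values are Bonferroni products `p ×
n_tests` (29 tests in the standard screen: 4 PTM + 9 domain + 1
N-degron + 15 disorder), left uncapped so they remain comparable across
screens of different size.

## Phosphosite PWMs

Each motif's matrix is estimated from a foreground set of equal-length
windows (known phosphosites matching that motif). A cell is

    log((F + P) / BG),   P = BG / 10,

with `F` the column-wise foreground frequency of the residue and `BG` its
background frequency; the printed form of this estimator sums over the
foreground sequences, which collapses to frequency estimation, and only
that reading yields a position-specific matrix. The pseudocount keeps all
cells finite. A window scores the sum of its cells; a sequence scores the
maximum over all matrices and all ungapped placements. Windows containing
non-standard residues are skipped; a sequence shorter than every matrix
returns an *absent* sentinel. No width normalization is applied (whether
the match score should be length-normalized is left open; the choice is
recorded here and configurable by post-scaling). Background frequencies
default to the residue frequencies of the supplied sequence collection,
floored at 1e-4 and renormalized so no residue zeroes out the
pseudocount.

## Sequence SVM

The 1-spectrum kernel counts length-1 substrings, so it reduces to the
dot product of amino-acid composition vectors; the classifier is a linear
soft-margin SVM (`sklearn.svm.SVC(kernel="linear")`, cost 1.0 — the
regularizer is not otherwise constrained and 1.0 is recorded in the model
document). Composition vectors are length-normalized frequencies, which
removes the protein-length confound of raw counts. To calibrate without
over-fitting, the training sample is halved by a seeded stratified split:
the first half fits the SVM, the second fits one Gaussian per class to
the decision scores by maximum likelihood (variances floored at 1e-6 so a
degenerate half cannot produce infinite densities). Priors are the class
proportions of the training sample. The class posterior is

    P(stable | s) = π_s N(s; μ_s, σ_s²) / Σ_c π_c N(s; μ_c, σ_c²).

## The hybrid network

The joint factorizes as `P(X_1..X_N) = Π_i P(X_i | pa(X_i))` over 20
Boolean nodes and up to 3 continuous leaves:

* 16 observable Boolean roots (N-terminal flag, 4 PTM, 9 domain, 2
  disorder), learned as unconditional tables;
* latent **PTM** and **Domain** aggregators, each a leaky noisy-OR of its
  observables: `P(child = 1 | active set S) = 1 − (1 − c0) Π_{i∈S} q_i`.
  The leak is included (init 0.05, learnable) because without it a latent
  can never fire when all its inputs are false, which zeroes likelihoods
  on realistic data;
* a latent **Disorder** aggregator with a plain 4-row table (the noisy-OR
  assumption is stated only for the PTM and Domain aggregators);
* **Stability**, a table over its 4 parents (N-terms, PTM, Domain,
  Disorder) — 16 rows;
* continuous leaves with one Gaussian per parent state ("Gaussian density
  tables"): the sequence-SVM score under Stability, and the two PWM
  maxima under the two phosphorylation flags, which lets a PWM score
  speak to a phosphorylation status that the annotations leave unknown.

Variants: **BN+SVM** is the full model; **BN** drops the sequence leaf;
**SVM** keeps only Stability and the sequence leaf (and then reproduces
the calibrated SVM posterior exactly — asserted in tests).

**Inference** is exact: unobserved discrete nodes are summed out by
enumeration, vectorized over records grouped by missingness pattern;
continuous evidence enters as density weights, absent leaves contribute
no factor. The network is small (≤ 2^20 discrete assignments, and far
fewer once evidence is in), so no approximation is warranted.

**Learning** is expectation-maximization. The E-step computes exact
posteriors over all unobserved discrete nodes (the three aggregators
always; observables wherever a record's annotation is unknown). The
M-step re-estimates tables from expected counts plus a Laplace
pseudocount of 1.0, noisy-OR parameters by bounded L-BFGS-B maximization
of the expected log-likelihood (no closed form exists for the leaky
noisy-OR; the step is accepted only if it does not worsen the objective),
and Gaussian tables from posterior-weighted moments with the variance
floor. The pseudocount makes the monitored objective the penalized (MAP)
log-likelihood — log-likelihood plus the Dirichlet smoothing prior —
which EM guarantees non-decreasing; the trainer asserts this every
iteration (tolerance 1e-9) and raises on violation, since a decrease can
only mean a defective M-step. With pseudocount 0 the objective is the raw
observed-data log-likelihood. Stopping: relative objective change below
1e-6 (default) or 200 iterations. Initialization is seeded: root tables
near 0.5, multi-parent tables of the aggregators mildly monotone in the
number of active parents (this anchors each latent's polarity, which is
otherwise only identified up to a flip), the Stability table near
uniform, Gaussians from the moments of records whose parent is observed.
Smoothing means every learned table entry is strictly positive, so any
schema-legal evidence pattern — including ones never seen in training —
receives a score strictly inside (0, 1), never a degenerate 0/1.

**Identifiability.** A latent aggregator whose only child is Stability is
weakly identified: its conditional distribution can be traded against the
Stability table along directions that barely move the observable
likelihood (for the leaky noisy-OR there is an exact one-parameter family
rescaling the leak; with three latent layers the profile likelihood is
nearly flat more broadly at realistic sample sizes). This does not hurt
prediction — equivalent parameterizations score proteins identically —
but it means individual parameters should not be over-interpreted.
Parameter-recovery experiments therefore use a dedicated ground truth
with balanced parent marginals (each Stability row receives ≈ n/16 of
the sample), high-contrast rows (0.94/0.06, where binomial error is
small) and the aggregator CPDs clamped at truth
(`EmOptions.frozen_nodes`), so the measured error reflects the estimator
rather than the flat geometry; `EmOptions.learn_leak=False` is available
to pin the exact leak-rescaling family in other studies.

## Classification thresholds

A trained model emits `P(stable | evidence)`. Proteome-style
classification buckets scores with two thresholds `(lo, hi)`: below `lo`
unstable, above `hi` stable, otherwise non-assigned — a partition with no
gaps or overlaps. The conventional operating points are (0.2, 0.75) for a
model trained on the full benchmark and (0.3, 0.7) for the trimmed
protocol.

## Evaluation protocol

Repeated stratified k-fold cross-validation: per repeat (seeded `seed +
r`), a stratified fold assignment; per fold, *everything* is fit on the
training folds only — the PWM background, the SVM's calibration
half-split, the EM run — and the held-out fold is scored. Held-out scores
are pooled per repeat; AUC is computed by the rank (Mann–Whitney)
formulation with half-credit ties (`sklearn.metrics.roc_auc_score`); the
decision threshold is the pooled-score cutoff maximizing the F-score
(ties resolve to the lowest candidate), and sensitivity, specificity and
MCC are reported at it. Means and standard deviations are taken across
repeats (matching a report of consistency over multiple CV runs rather
than fold-level spread). Folds are re-drawn (up to 10 times) if a
training fold lacks a class. The comparison baseline is a
nearest-neighbour margin `D⁻ − D⁺` under 1-cosine distance — the
difference between the minimum distances to the negative and positive
training vectors — computed on whatever feature matrix the caller
supplies.

## Synthetic benchmark

The generator emulates the *shape* of the real inputs with planted ground
truth; every generator is a pure function of (config, seed).

* **7-bin table**: Dirichlet draws (concentration 200) around three
  prototypes concentrated in R1+R2, R3+R4 and R5–R7, with default counts
  80 / 240 / 80 — the ≈20%/60%/20% split of the motivating data.
* **Feature records**: exact ancestral samples from a known
  parameterization of the full network whose directions encode the
  study's qualitative findings (PTMs raise the stable probability,
  domain hits — dominated by transmembrane and signal peptide — and
  destabilizing N-termini lower it, high disorder raises it). Default
  sizes 743 stable / 794 unstable (300/227 for the trimmed protocol), so
  the 10-fold × 5 and 25-fold harness paths are exercised at the
  published data shape. Samples are collected until the class counts are
  met; `simulate_ancestral_records` skips the balancing when the untilted
  joint is needed (recovery studies). PTM flags are hidden with
  probability 0.1 to emulate silent annotation sources, and 2% of
  N-termini are unknown ('X').
* **Sequences**: residues drawn from a class composition profile
  (stable proteins boost E, D, K, N by ×1.6 over a human-like
  background); the N-terminal residue realizes the record's degron flag
  through the Met-removal rule in reverse (signal-peptide records carry a
  cleavage position at 15–30 and plant the flag's residue after it);
  phosphosite motif windows (synthetic motifs: a fixed acceptor residue
  plus two conserved flanking positions, 30 foreground windows each) are
  planted at uniform positions with class-specific probability 0.7
  (stable) / 0.25 (unstable). Sequence lengths are log-normal around 300
  residues, clipped to [60, 2000].

What the fixtures do **not** emulate: real domain co-occurrence,
homology, evolutionary composition structure, realistic disorder/PTM
correlations, or any actual proteome content. Passing the closed-loop
tests therefore demonstrates that the machinery is correct and that the
pipeline recovers planted signal at realistic sizes — not that the model
reaches any particular accuracy on real profiling data.

## Numerical choices

* Probabilities are clipped at 1e-12 inside log-space factor evaluation;
  noisy-OR bounds are q ∈ [1e-4, 1], leak ∈ [1e-4, 1−1e-4].
* Gaussian variances are floored at 1e-6 everywhere.
* Bin vectors renormalize on load when their sum is within 0.05 of 1,
  else the row errors.
* CV problem sizes in the shipped tests and the reproduction script are
  the full 743/794 benchmark for the headline protocol and smaller draws
  for unit-level checks; EM inside cross-validation runs with
  `max_iter = 100, tol = 1e-5`, which the predictive scores are
  insensitive to (parameter drift along the flat directions does not move
  the posterior).
* Distance ties in clustering resolve by the linkage implementation's
  deterministic ordering; max-F threshold ties resolve to the lowest
  candidate.

## Known limitations

* Exact enumeration is exponential in the number of *unobserved* discrete
  nodes; fine for this 20-node network, not for materially larger ones.
* The noisy-OR M-step is a numerical maximization, so EM iterations cost
  more than closed-form updates (immaterial at these sizes).
* Latent-layer parameters are weakly identified (see above); compare
  models by predictive scores, not by individual aggregator parameters.
* The class-balanced benchmark intentionally tilts the class prior;
  models trained on it inherit that prior, as any classifier trained on
  balanced data does.
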