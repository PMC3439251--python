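"""End-to-end glue: turn raw inputs (sequences, annotations, motif
windows, labels) into trained models and cross-validatable scorers.

Everything a variant needs to fit — PWM background, the SVM half-split,
EM — happens inside the model builder on the training items only, so the
cross-validation harness never leaks held-out information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import bn, evaluation, pwm, svm
from .features import FeatureVector, PWM_KINDS, build_feature_vectors
from .io import AnnotationRecord


@dataclass
class StabilityData:
    """The joined raw inputs for model training and evaluation."""

    sequences: dict[str, str]
    annotations: list[AnnotationRecord]
    labels: dict[str, str]  # id -> "stable" / "unstable"
    motif_windows: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def training_ids(self) -> list[str]:
        return [a.protein_id for a in self.annotations if a.protein_id in self.labels]


def build_pwm_sets(
    motif_windows: dict[str, dict[str, list[str]]],
    background: np.ndarray,
) -> dict[str, pwm.PwmSet]:
    sets = {}
    for kind in PWM_KINDS:
        models = [
            pwm.build_pwm(motif_id, windows, background)
            for motif_id, windows in sorted(motif_windows.get(kind, {}).items())
        ]
        if models:
            sets[kind] = pwm.PwmSet(kind=kind, models=models)
    return sets


@dataclass
class TrainedModel:
    variant: str
    spec: bn.NetworkSpec
    params: bn.Parameters
    pwm_sets: dict[str, pwm.PwmSet]
    svm_model: Optional[svm.CalibratedSvm]
    em_result: Optional[bn.EmResult] = None

    def vectors_for(self, data: StabilityData, ids: Sequence[str]) -> list[FeatureVector]:
        anns = {a.protein_id: a for a in data.annotations}
        return build_feature_vectors(
            data.sequences,
            [anns[i] for i in ids],
            pwm_sets=self.pwm_sets,
            svm_model=self.svm_model,
            labels=data.labels,
        )

    def score_ids(self, data: StabilityData, ids: Sequence[str]) -> np.ndarray:
        vectors = self.vectors_for(data, ids)
        cols = bn.vectors_to_data(self.spec, vectors, with_labels=False)
        return bn.score_records(self.spec, self.params, cols)


def train_variant(
    data: StabilityData,
    train_ids: Sequence[str],
    variant: str,
    seed: int,
    em_options: Optional[bn.EmOptions] = None,
) -> TrainedModel:
    """Fit one model variant on the given training ids.

    ``svm``: Stability prior from class proportions (Laplace-smoothed) and
    the calibrated score Gaussians — no EM. ``bn`` / ``bn_svm``: the full
    network trained by EM; the sequence SVM (for ``bn_svm``) and the PWM
    background are fit on the training ids only.
    """
    train_ids = list(train_ids)
    labels = [data.labels[i] for i in train_ids]
    train_seqs = [data.sequences[i] for i in train_ids if i in data.sequences]

    svm_model = None
    if variant in ("svm", "bn_svm"):
        seq_ids = [i for i in train_ids if i in data.sequences]
        svm_model = svm.train_calibrated_svm(
            [data.sequences[i] for i in seq_ids],
            [data.labels[i] for i in seq_ids],
            seed=seed,
        )

    pwm_sets: dict[str, pwm.PwmSet] = {}
    if variant in ("bn", "bn_svm") and data.motif_windows and train_seqs:
        background = pwm.background_from_sequences(train_seqs)
        pwm_sets = build_pwm_sets(data.motif_windows, background)

    spec = bn.build_model(variant)
    if variant == "svm":
        n_stable = sum(1 for l in labels if l == "stable")
        n = len(labels)
        p1 = (n_stable + 1.0) / (n + 2.0)
        params: bn.Parameters = {
            bn.STABILITY: bn.CptParams(np.array([1.0 - p1, p1])),
            bn.SVM_LEAF: bn.GaussianTable(
                mean=np.array(
                    [svm_model.means["unstable"], svm_model.means["stable"]]
                ),
                var=np.array(
                    [svm_model.variances["unstable"], svm_model.variances["stable"]]
                ),
            ),
        }
        return TrainedModel(variant, spec, params, pwm_sets, svm_model)

    model = TrainedModel(variant, spec, {}, pwm_sets, svm_model)
    train_vectors = model.vectors_for(data, train_ids)
    cols = bn.vectors_to_data(spec, train_vectors, with_labels=True)
    options = em_options or bn.EmOptions(seed=seed)
    options = bn.EmOptions(**{**options.__dict__, "seed": seed})
    result = bn.em_train(spec, cols, options)
    model.params = result.params
    model.em_result = result
    return model


def make_model_builder(
    data: StabilityData,
    variant: str,
    em_options: Optional[bn.EmOptions] = None,
):
    """Adapter giving :func:`stabnet.evaluation.cross_validate` a scorer.

    Items are protein ids; the returned builder trains the variant on the
    training ids and scores held-out ids with the fitted model.
    """

    def builder(train_ids, train_labels, seed):
        model = train_variant(data, train_ids, variant, seed, em_options)
        return lambda test_ids: model.score_ids(data, test_ids)

    return builder


# ---------------------------------------------------------------------------
# Nearest-neighbour baseline over encoded feature vectors


def encode_vectors(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Numeric matrix for distance-based baselines.

    Booleans map to 0/1 with unknown as 0.5; continuous scores are kept
    as-is with absent values at 0 (callers may standardize columns).
    """
    rows = []
    for v in vectors:
        row = [0.5 if v.n_term_stabilizing is None else float(v.n_term_stabilizing)]
        row += [0.5 if x is None else float(x) for x in v.ptm_flags.values()]
        row += [float(x) for x in v.domain_flags.values()]
        row += [float(x) for x in v.disorder_flags.values()]
        row += [0.0 if v.pwm_scores.get(k) is None else v.pwm_scores[k] for k in PWM_KINDS]
        row.append(0.0 if v.svm_score is None else v.svm_score)
        rows.append(row)
    return np.array(rows)


def make_nn_builder(data: StabilityData):
    """Nearest-neighbour (1-cosine distance) baseline over raw features."""
    anns = {a.protein_id: a for a in data.annotations}

    def vectors_for(ids):
        return build_feature_vectors(data.sequences, [anns[i] for i in ids])

    def builder(train_ids, train_labels, seed):
        X = encode_vectors(vectors_for(train_ids))
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd + 1e-9  # avoid exact zero-norm rows
        baseline = evaluation.NnBaseline(
            X=Xz, labels=np.array([l == "stable" for l in train_labels])
        )

        def scorer(test_ids):
            Q = (encode_vectors(vectors_for(test_ids)) - mu) / sd + 1e-9
            return np.array([evaluation.nn_score(baseline, q) for q in Q])

        return scorer

    return builder
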