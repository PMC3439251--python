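"""1-spectrum-kernel sequence SVM with Gaussian score calibration.

The 1-spectrum kernel reduces to the dot product of amino-acid composition
vectors, so the classifier is a linear SVM over 20 composition features.
To turn the margin score into class-conditional densities without
over-fitting, the training sample is halved: the first half trains the
SVM, the second half fits one Gaussian per class to the decision scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .alphabet import AA_INDEX, N_RESIDUES

VARIANCE_FLOOR = 1e-6
LABEL_TO_INT = {"unstable": 0, "stable": 1}


def spectrum_features(
    sequence: str, normalize: bool = True, return_ignored: bool = False
):
    """Map a sequence to its 1-spectrum (composition) vector.

    In frequency mode (default) the counts are divided by the number of
    standard residues, removing the protein-length confound. Non-standard
    symbols are ignored; pass ``return_ignored=True`` to also get their
    count.
    """
    counts = np.zeros(N_RESIDUES)
    ignored = 0
    for residue in sequence.upper():
        idx = AA_INDEX.get(residue)
        if idx is None:
            ignored += 1
        else:
            counts[idx] += 1
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return (counts, ignored) if return_ignored else counts


def spectrum_kernel(a: str, b: str) -> float:
    """1-spectrum kernel value: dot product of raw composition counts."""
    return float(
        spectrum_features(a, normalize=False) @ spectrum_features(b, normalize=False)
    )


@dataclass
class CalibratedSvm:
    """Linear decision function plus per-class score Gaussians and priors."""

    weights: np.ndarray  # (20,)
    offset: float
    means: dict[str, float]  # class -> mean of decision scores
    variances: dict[str, float]  # class -> variance (floored)
    priors: dict[str, float]  # class -> prior probability
    normalize: bool = True
    seed: Optional[int] = None
    cost: float = 1.0


def decision_score(model: CalibratedSvm, sequence: str) -> float:
    x = spectrum_features(sequence, normalize=model.normalize)
    return float(x @ model.weights + model.offset)


def train_calibrated_svm(
    sequences: Sequence[str],
    labels: Sequence[str],
    seed: int,
    cost: float = 1.0,
    normalize: bool = True,
) -> CalibratedSvm:
    """Train the sequence SVM and calibrate its score distribution.

    The stratified half-split is seeded; the first half trains the
    max-margin classifier, the second fits the class-conditional Gaussians
    by maximum likelihood. Priors are the class proportions of the full
    training sample. Scores are oriented so that larger means more stable.
    """
    labels = list(labels)
    if set(labels) - set(LABEL_TO_INT):
        raise ValueError(f"labels must be in {sorted(LABEL_TO_INT)}")
    y = np.array([LABEL_TO_INT[l] for l in labels])
    if len(set(y)) < 2:
        raise ValueError("both classes required for SVM training")
    X = np.vstack([spectrum_features(s, normalize=normalize) for s in sequences])

    X_fit, X_cal, y_fit, y_cal = train_test_split(
        X, y, test_size=0.5, random_state=seed, stratify=y
    )
    if len(set(y_fit)) < 2 or len(set(y_cal)) < 2:
        raise ValueError(
            "a half-split ended up single-class; re-split with a different seed"
        )

    clf = SVC(kernel="linear", C=cost)
    clf.fit(X_fit, y_fit)
    weights = clf.coef_.ravel().copy()
    offset = float(clf.intercept_[0])
    # sklearn orients decision_function toward the larger class label (1 =
    # stable), which is the orientation we document.

    cal_scores = X_cal @ weights + offset
    means, variances = {}, {}
    for name, code in LABEL_TO_INT.items():
        s = cal_scores[y_cal == code]
        means[name] = float(s.mean())
        variances[name] = float(max(s.var(), VARIANCE_FLOOR))
    n = len(y)
    priors = {name: float(np.sum(y == code) / n) for name, code in LABEL_TO_INT.items()}
    return CalibratedSvm(
        weights=weights,
        offset=offset,
        means=means,
        variances=variances,
        priors=priors,
        normalize=normalize,
        seed=seed,
        cost=cost,
    )


def _normal_pdf(x: float, mean: float, var: float) -> float:
    return float(np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var))


def svm_posterior(score: float, model: CalibratedSvm) -> float:
    """P(stable | score) from the calibrated class Gaussians and priors."""
    num = model.priors["stable"] * _normal_pdf(
        score, model.means["stable"], model.variances["stable"]
    )
    den = num + model.priors["unstable"] * _normal_pdf(
        score, model.means["unstable"], model.variances["unstable"]
    )
    if den <= 0:
        raise ValueError("zero total density at score; calibration degenerate")
    return num / den


# ---------------------------------------------------------------------------
# Serialization


def svm_to_dict(model: CalibratedSvm) -> dict:
    return {
        "weights": model.weights.tolist(),
        "offset": model.offset,
        "means": model.means,
        "variances": model.variances,
        "priors": model.priors,
        "normalize": model.normalize,
        "seed": model.seed,
        "cost": model.cost,
    }


def svm_from_dict(doc: dict) -> CalibratedSvm:
    return CalibratedSvm(
        weights=np.array(doc["weights"], dtype=float),
        offset=float(doc["offset"]),
        means={k: float(v) for k, v in doc["means"].items()},
        variances={k: float(v) for k, v in doc["variances"].items()},
        priors={k: float(v) for k, v in doc["priors"].items()},
        normalize=bool(doc["normalize"]),
        seed=doc.get("seed"),
        cost=float(doc.get("cost", 1.0)),
    )


def save_svm(model: CalibratedSvm, path) -> None:
    with open(path, "w") as fh:
        json.dump(svm_to_dict(model), fh, indent=1)


def load_svm(path) -> CalibratedSvm:
    with open(path) as fh:
        return svm_from_dict(json.load(fh))
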