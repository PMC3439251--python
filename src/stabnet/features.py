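"""Feature extraction: N-end-rule degron status, disorder binning, the
19-component feature vector, and Fisher-exact enrichment statistics.

The per-protein observation record combines
1 N-terminal flag + 4 PTM flags + 9 domain flags + 2 high-disorder flags
+ 2 phosphosite PWM scores + 1 sequence-SVM score = 19 components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .alphabet import AA_INDEX

# Canonical observable names, shared with the network schema.
PTM_FEATURES = ("tyr_phos", "ser_thr_phos", "acetylation", "glycosylation")
DOMAIN_FEATURES = (
    "transmembrane",
    "signal_peptide",
    "loops_coils_motif",
    "immunoglobulin",
    "immunoglobulin_like",
    "immunoglobulin_c",
    "zinc_finger_c2",
    "cadherin",
    "rna_recognition_motif",
)
DISORDER_TYPES = ("loops_coils", "hot_loops", "rem465")
# the network consumes only the 80-100% indicators of these two types
DISORDER_FEATURES = ("disorder_loops_coils_80", "disorder_hot_loops_80")
_DISORDER_FLAG_TYPE = {
    "disorder_loops_coils_80": "loops_coils",
    "disorder_hot_loops_80": "hot_loops",
}
PWM_KINDS = ("tyrosine", "ser_thr")

#: residues whose exposure at the mature N-terminus destabilizes a protein
#: (original N-end rule; primary + secondary + tertiary destabilizing sets)
DESTABILIZING_RESIDUES = frozenset("RKHFLWIY")
#: second residues that trigger removal of the initiator methionine
MET_REMOVAL_SECOND = frozenset("CGASTVP")


# ---------------------------------------------------------------------------
# N-end rule


def mature_n_terminus(sequence: str, cleavage_pos: Optional[int] = None) -> str:
    """Return the residue exposed at the N-terminus of the mature chain.

    With a signal peptide cleaved after 1-based position ``cleavage_pos``,
    the mature chain starts at ``cleavage_pos + 1``. Without one, the
    initiator Met is removed when the second residue is small (C, G, A, S,
    T, V or P), exposing that residue; otherwise the Met (or whatever the
    first residue is) stands.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    if cleavage_pos is not None:
        if not (1 <= cleavage_pos < len(sequence)):
            raise ValueError(
                f"cleavage position {cleavage_pos} outside sequence of "
                f"length {len(sequence)}"
            )
        return sequence[cleavage_pos]  # 1-based pos+1 == 0-based index pos
    if sequence[0] == "M" and sequence[1] in MET_REMOVAL_SECOND:
        return sequence[1]
    return sequence[0]


def classify_n_degron(residue: str) -> Optional[str]:
    """Classify a mature N-terminal residue as stabilizing or destabilizing.

    Returns ``"destabilizing"`` for R, K, H, F, L, W, I, Y; ``"stabilizing"``
    for the other 12 standard residues; ``None`` for non-standard symbols
    (e.g. 'X'), which the feature layer treats as an unknown observation.
    """
    residue = residue.upper()
    if residue not in AA_INDEX:
        return None
    return "destabilizing" if residue in DESTABILIZING_RESIDUES else "stabilizing"


def n_term_stabilizing(
    sequence: str, cleavage_pos: Optional[int] = None
) -> Optional[bool]:
    """Boolean form of the degron call; ``None`` when the residue is unknown."""
    call = classify_n_degron(mature_n_terminus(sequence, cleavage_pos))
    if call is None:
        return None
    return call == "stabilizing"


# ---------------------------------------------------------------------------
# Disorder binning

_LEVEL_EDGES = (0.2, 0.4, 0.6, 0.8)


def disorder_level(fraction: float) -> int:
    """Map a disordered-sequence fraction to level 1..5.

    Level 1 covers [0, 0.2]; each subsequent level is a half-open (lo, hi]
    20%-wide band, so 0.2 -> 1 and 1.0 -> 5.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"disorder fraction {fraction} outside [0, 1]")
    return 1 + int(np.searchsorted(_LEVEL_EDGES, fraction, side="left"))


# ---------------------------------------------------------------------------
# Feature vectors


@dataclass
class FeatureVector:
    """The 19-component observation record consumed by the stability models.

    Tri-state flags use ``True``/``False``/``None`` (unknown); the network
    marginalizes over unknowns. ``pwm_scores`` may hold ``None`` when the
    sequence is shorter than every matrix, and ``svm_score`` is only present
    when a trained sequence SVM was supplied.
    """

    protein_id: str
    n_term_stabilizing: Optional[bool] = None
    ptm_flags: dict[str, Optional[bool]] = field(default_factory=dict)
    domain_flags: dict[str, bool] = field(default_factory=dict)
    disorder_flags: dict[str, bool] = field(default_factory=dict)
    pwm_scores: dict[str, Optional[float]] = field(default_factory=dict)
    svm_score: Optional[float] = None
    label: Optional[str] = None  # "stable" / "unstable" when known

    def n_components(self) -> int:
        n = 1 + len(self.ptm_flags) + len(self.domain_flags) + len(self.disorder_flags)
        n += len(self.pwm_scores)
        if self.svm_score is not None:
            n += 1
        return n


def build_feature_vectors(
    sequences: dict[str, str],
    annotations: Sequence,
    pwm_sets=None,
    svm_model=None,
    labels: Optional[dict[str, str]] = None,
) -> list[FeatureVector]:
    """Join sequences and annotations into feature vectors.

    ``pwm_sets`` is a mapping kind -> :class:`~stabnet.pwm.PwmSet` for the
    tyrosine and ser/thr matrices; ``svm_model`` a trained
    :class:`~stabnet.svm.CalibratedSvm`. Proteins missing a sequence get
    their sequence-derived fields marked unknown rather than being dropped.
    """
    from . import pwm as pwm_mod
    from . import svm as svm_mod

    vectors = []
    for ann in annotations:
        pid = ann.protein_id
        seq = sequences.get(pid)
        nterm: Optional[bool] = None
        pwm_scores: dict[str, Optional[float]] = {k: None for k in PWM_KINDS}
        svm_score = None
        if seq is not None and len(seq) >= 2:
            nterm = n_term_stabilizing(seq, ann.signal_cleavage_pos)
            if pwm_sets:
                for kind in PWM_KINDS:
                    if kind in pwm_sets:
                        pwm_scores[kind] = pwm_mod.scan_sequence(seq, pwm_sets[kind])
            if svm_model is not None:
                svm_score = svm_mod.decision_score(svm_model, seq)
        disorder_flags = {
            flag: disorder_level(ann.disorder_fractions.get(dtype, 0.0)) == 5
            for flag, dtype in _DISORDER_FLAG_TYPE.items()
        }
        vectors.append(
            FeatureVector(
                protein_id=pid,
                n_term_stabilizing=nterm,
                ptm_flags={k: ann.ptm_flags.get(k) for k in PTM_FEATURES},
                domain_flags={k: bool(ann.domain_flags.get(k, False)) for k in DOMAIN_FEATURES},
                disorder_flags=disorder_flags,
                pwm_scores=pwm_scores,
                svm_score=svm_score,
                label=None if labels is None else labels.get(pid),
            )
        )
    return vectors


# ---------------------------------------------------------------------------
# Enrichment statistics


@dataclass
class EnrichmentResult:
    feature_name: str
    direction: Optional[str]  # "over" / "under" / None when undefined
    contingency: np.ndarray  # [[in&present, in&absent], [out&present, out&absent]]
    p_value: float
    e_value: float


def enrichment_test(
    in_class: Sequence[bool],
    feature_presence: Sequence[bool],
    n_tests: int,
    feature_name: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher exact test for a feature in one stability class.

    The 2x2 table crosses membership of the target class (vs all other
    proteins) with feature presence. The direction of the effect is read
    off the sample odds ratio; the E-value is the Bonferroni-scaled
    p-value ``p * n_tests`` (not capped at 1, matching how corrected
    enrichment values are conventionally reported).
    """
    in_class = np.asarray(in_class, dtype=bool)
    present = np.asarray(feature_presence, dtype=bool)
    if in_class.shape != present.shape:
        raise ValueError("label and presence vectors differ in length")
    a = int(np.sum(in_class & present))
    b = int(np.sum(in_class & ~present))
    c = int(np.sum(~in_class & present))
    d = int(np.sum(~in_class & ~present))
    table = np.array([[a, b], [c, d]])
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return EnrichmentResult(feature_name, None, table, 1.0, float(n_tests))
    _, p = fisher_exact(table, alternative="two-sided")
    # sample odds ratio; infinite/zero cells still give a usable direction
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else math.inf
    if a * d == b * c:
        direction = None
    else:
        direction = "over" if a * d > b * c else "under"
    return EnrichmentResult(feature_name, direction, table, float(p), float(p) * n_tests)


def enrichment_analysis(
    annotations: Sequence,
    sequences: dict[str, str],
    class_of: dict[str, str],
    target_class: str,
) -> list[EnrichmentResult]:
    """Run the full feature-enrichment screen for one stability class.

    Tests the 4 PTMs, 9 domain/architecture types, the destabilizing
    N-degron, and all 15 disorder type x level indicators (3 types x 5
    levels), i.e. 29 tests; E-values are Bonferroni-corrected for that
    count.
    """
    anns = [a for a in annotations if a.protein_id in class_of]
    in_class = [class_of[a.protein_id] == target_class for a in anns]

    tests: list[tuple[str, list[bool]]] = []
    for name in PTM_FEATURES:
        tests.append((name, [bool(a.ptm_flags.get(name)) for a in anns]))
    for name in DOMAIN_FEATURES:
        tests.append((name, [bool(a.domain_flags.get(name, False)) for a in anns]))

    def destabilizing(a) -> bool:
        seq = sequences.get(a.protein_id)
        if seq is None or len(seq) < 2:
            return False
        return n_term_stabilizing(seq, a.signal_cleavage_pos) is False

    tests.append(("n_degron", [destabilizing(a) for a in anns]))
    for dtype in DISORDER_TYPES:
        levels = [disorder_level(a.disorder_fractions.get(dtype, 0.0)) for a in anns]
        for lvl in range(1, 6):
            tests.append((f"{dtype}_level{lvl}", [l == lvl for l in levels]))

    n_tests = len(tests)
    return [
        enrichment_test(in_class, presence, n_tests, feature_name=name)
        for name, presence in tests
    ]
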