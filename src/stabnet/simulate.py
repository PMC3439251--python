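"""Synthetic fixtures with planted ground truth for every pipeline input.

The generator emulates the shape of the real study inputs — a 7-bin FACS
stability table with three latent groups, annotation flags sampled from a
known stability network, sequences whose composition and N-terminal
residue carry the planted class signal, and phosphosite motif windows —
without pretending to be real proteome content. Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import bn
from .alphabet import AMINO_ACIDS, AA_INDEX
from .features import (
    DESTABILIZING_RESIDUES,
    DISORDER_FEATURES,
    DOMAIN_FEATURES,
    MET_REMOVAL_SECOND,
    PTM_FEATURES,
    PWM_KINDS,
    FeatureVector,
)
from .io import AnnotationRecord, GpspRecord

STABILIZING_RESIDUES = [a for a in AMINO_ACIDS if a not in DESTABILIZING_RESIDUES]

# human-like background amino-acid frequencies (order = AMINO_ACIDS)
BASE_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.036,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}
#: residues reported positively correlated with stability
STABILITY_ENRICHED = ("E", "D", "K", "N")


def _composition_vector(boost: dict[str, float]) -> np.ndarray:
    freq = np.array([BASE_COMPOSITION[a] for a in AMINO_ACIDS])
    for res, factor in boost.items():
        freq[AA_INDEX[res]] *= factor
    return freq / freq.sum()


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the shape of the published data: 743 stable / 794
    unstable training records (300/227 for the trimmed protocol) and a
    GPSP table splitting roughly 20% / 20% / 60% across the unstable /
    stable / non-assigned groups.
    """

    # BN-side records
    n_stable: int = 743
    n_unstable: int = 794
    ptm_missing_prob: float = 0.1  # emulates silent annotation sources
    n_term_unknown_prob: float = 0.02  # sequences starting with 'X'

    # GPSP table: counts for (unstable, non_assigned, stable)
    gpsp_counts: tuple[int, int, int] = (80, 240, 80)
    gpsp_concentration: float = 200.0
    gpsp_prototypes: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.38, 0.30, 0.12, 0.08, 0.05, 0.04, 0.03],  # unstable: R1+R2
                [0.06, 0.10, 0.34, 0.30, 0.12, 0.05, 0.03],  # middle: R3+R4
                [0.03, 0.04, 0.06, 0.12, 0.22, 0.26, 0.27],  # stable: R5-R7
            ]
        )
    )

    # sequences
    seq_len_log_mean: float = float(np.log(300.0))
    seq_len_log_sigma: float = 0.35
    seq_len_min: int = 60
    seq_len_max: int = 2000
    stable_boost: float = 1.6  # composition multiplier for E, D, K, N
    motif_plant_prob: dict = field(
        default_factory=lambda: {"stable": 0.7, "unstable": 0.25}
    )

    # synthetic phospho motifs
    n_motifs_per_kind: int = 4
    motif_width: int = 7
    windows_per_motif: int = 30

    def class_composition(self, label: str) -> np.ndarray:
        if label == "stable":
            return _composition_vector(
                {r: self.stable_boost for r in STABILITY_ENRICHED}
            )
        return _composition_vector({})


# ---------------------------------------------------------------------------
# Ground-truth network


def default_ground_truth() -> tuple[bn.NetworkSpec, bn.Parameters]:
    """The known parameterization the fixtures sample from.

    Directions encode the study's qualitative findings: PTMs raise the
    probability of the stable class, domain/architecture hits (dominated
    by transmembrane and signal-peptide) lower it, a destabilizing mature
    N-terminus lowers it, and high structural disorder raises it. Root
    priors sit in a mid range so every Stability parent configuration
    keeps appreciable mass (the network is identifiable from realistic
    sample sizes).
    """
    spec = bn.build_model("bn_svm")
    params: bn.Parameters = {}

    def prior(p1: float) -> bn.CptParams:
        return bn.CptParams(np.array([1.0 - p1, p1]))

    params[bn.N_TERM] = prior(0.7)
    ptm_priors = {"tyr_phos": 0.3, "ser_thr_phos": 0.5, "acetylation": 0.2, "glycosylation": 0.05}
    for name in PTM_FEATURES:
        params[name] = prior(ptm_priors[name])
    domain_priors = {
        "transmembrane": 0.30,
        "signal_peptide": 0.25,
        "loops_coils_motif": 0.20,
        "immunoglobulin": 0.10,
        "immunoglobulin_like": 0.10,
        "immunoglobulin_c": 0.08,
        "zinc_finger_c2": 0.08,
        "cadherin": 0.05,
        "rna_recognition_motif": 0.08,
    }
    for name in DOMAIN_FEATURES:
        params[name] = prior(domain_priors[name])
    params["disorder_loops_coils_80"] = prior(0.20)
    params["disorder_hot_loops_80"] = prior(0.18)

    params[bn.PTM_LATENT] = bn.NoisyOrParams(
        q=np.array([0.40, 0.45, 0.35, 0.90]), c0=0.05
    )
    params[bn.DOMAIN_LATENT] = bn.NoisyOrParams(
        q=np.array([0.25, 0.30, 0.70, 0.75, 0.75, 0.80, 0.80, 0.85, 0.80]), c0=0.05
    )
    dis = np.empty((2, 2, 2))
    for lc in (0, 1):
        for hl in (0, 1):
            p1 = {(0, 0): 0.08, (0, 1): 0.60, (1, 0): 0.60, (1, 1): 0.90}[(lc, hl)]
            dis[lc, hl] = (1.0 - p1, p1)
    params[bn.DISORDER_LATENT] = bn.CptParams(dis)

    stab = np.empty((2, 2, 2, 2, 2))
    for nterm in (0, 1):
        for ptm in (0, 1):
            for dom in (0, 1):
                for diso in (0, 1):
                    logit = -0.6 + 2.0 * nterm + 1.6 * ptm - 2.2 * dom + 1.0 * diso
                    p1 = 1.0 / (1.0 + np.exp(-logit))
                    stab[nterm, ptm, dom, diso] = (1.0 - p1, p1)
    params[bn.STABILITY] = bn.CptParams(stab)

    params[bn.SVM_LEAF] = bn.GaussianTable(
        mean=np.array([-1.0, 1.0]), var=np.array([1.0, 1.0])
    )
    params[bn.PWM_LEAVES["tyrosine"]] = bn.GaussianTable(
        mean=np.array([2.0, 6.0]), var=np.array([4.0, 4.0])
    )
    params[bn.PWM_LEAVES["ser_thr"]] = bn.GaussianTable(
        mean=np.array([2.0, 6.0]), var=np.array([4.0, 4.0])
    )
    return spec, params


def recovery_ground_truth() -> tuple[bn.NetworkSpec, bn.Parameters]:
    """A strongly-coupled parameterization for parameter-recovery studies.

    The default benchmark truth has deliberately moderate effect sizes;
    with three latent layers its likelihood is nearly flat along latent
    reparameterization directions, so finite-sample EM estimates wander
    there without being wrong about anything observable. Recovery studies
    instead need latents whose posteriors are close to 0/1 — strong
    noisy-OR inhibitions, a near-deterministic Disorder table and a
    high-contrast Stability table — so that every parameter is pinned by
    the data and estimation error reflects the estimator, not the
    geometry.
    """
    spec, params = default_ground_truth()
    params = dict(params)

    def prior(p1: float) -> bn.CptParams:
        return bn.CptParams(np.array([1.0 - p1, p1]))

    # roots chosen so each latent's marginal sits near 0.5: the 16
    # Stability parent configurations then share the sample about evenly
    params[bn.N_TERM] = prior(0.5)
    for name, p1 in zip(PTM_FEATURES, (0.22, 0.22, 0.18, 0.12)):
        params[name] = prior(p1)
    dom_priors = (0.20, 0.18, 0.10, 0.08, 0.08, 0.06, 0.06, 0.05, 0.06)
    for name, p1 in zip(DOMAIN_FEATURES, dom_priors):
        params[name] = prior(p1)
    params["disorder_loops_coils_80"] = prior(0.30)
    params["disorder_hot_loops_80"] = prior(0.30)

    params[bn.PTM_LATENT] = bn.NoisyOrParams(
        q=np.array([0.08, 0.08, 0.12, 0.25]), c0=0.02
    )
    params[bn.DOMAIN_LATENT] = bn.NoisyOrParams(
        q=np.array([0.10, 0.10, 0.30, 0.40, 0.40, 0.50, 0.50, 0.60, 0.50]), c0=0.02
    )
    dis = np.empty((2, 2, 2))
    for lc in (0, 1):
        for hl in (0, 1):
            p1 = {(0, 0): 0.02, (0, 1): 0.95, (1, 0): 0.95, (1, 1): 0.99}[(lc, hl)]
            dis[lc, hl] = (1.0 - p1, p1)
    params[bn.DISORDER_LATENT] = bn.CptParams(dis)
    # high-contrast rows: extreme probabilities have small binomial error
    stab = np.empty((2, 2, 2, 2, 2))
    for nterm in (0, 1):
        for ptm in (0, 1):
            for dom in (0, 1):
                for diso in (0, 1):
                    p1 = 0.94 if nterm + ptm + diso + (1 - dom) >= 2 else 0.06
                    stab[nterm, ptm, dom, diso] = (1.0 - p1, p1)
    params[bn.STABILITY] = bn.CptParams(stab)
    params[bn.SVM_LEAF] = bn.GaussianTable(
        mean=np.array([-1.5, 1.5]), var=np.array([1.0, 1.0])
    )
    params[bn.PWM_LEAVES["tyrosine"]] = bn.GaussianTable(
        mean=np.array([2.0, 8.0]), var=np.array([1.0, 1.0])
    )
    params[bn.PWM_LEAVES["ser_thr"]] = bn.GaussianTable(
        mean=np.array([2.0, 8.0]), var=np.array([1.0, 1.0])
    )
    return spec, params


def perturb_params(
    params: bn.Parameters, rng: np.random.Generator, scale: float = 0.1
) -> bn.Parameters:
    """Jitter a parameterization for recovery studies.

    Probabilities move by up to ``scale`` (clipped away from 0/1), Gaussian
    means by up to ``3 * scale`` and variances by up to 30% — a starting
    point that is wrong everywhere but in the right basin.
    """
    out: bn.Parameters = {}
    for name, p in params.items():
        if isinstance(p, bn.CptParams):
            p1 = np.clip(
                p.table[..., 1] + rng.uniform(-scale, scale, p.table[..., 1].shape),
                0.02,
                0.98,
            )
            out[name] = bn.CptParams(np.stack([1.0 - p1, p1], axis=-1))
        elif isinstance(p, bn.NoisyOrParams):
            q = np.clip(p.q + rng.uniform(-scale, scale, p.q.shape), 0.02, 1.0)
            out[name] = bn.NoisyOrParams(q=q, c0=p.c0)
        else:
            mean = p.mean + rng.uniform(-3 * scale, 3 * scale, p.mean.shape)
            var = p.var * rng.uniform(0.7, 1.3, p.var.shape)
            out[name] = bn.GaussianTable(mean=mean, var=np.maximum(var, bn.VARIANCE_FLOOR))
    return out


# ---------------------------------------------------------------------------
# GPSP table


GPSP_GROUPS = ("unstable", "non_assigned", "stable")


def simulate_gpsp(
    config: FixtureConfig, seed: int
) -> tuple[list[GpspRecord], list[str]]:
    """Dirichlet draws around the three stability-group prototypes."""
    if config.gpsp_concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    records, labels = [], []
    idx = 0
    for group, proto, count in zip(
        GPSP_GROUPS, config.gpsp_prototypes, config.gpsp_counts
    ):
        alpha = config.gpsp_concentration * np.asarray(proto, dtype=float)
        for _ in range(count):
            bins = rng.dirichlet(alpha)
            records.append(GpspRecord(f"g{idx:04d}", bins))
            labels.append(group)
            idx += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order], [labels[i] for i in order]


# ---------------------------------------------------------------------------
# BN records


def _truth_to_vectors(
    config: FixtureConfig,
    truth: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[FeatureVector]:
    n = len(truth[bn.STABILITY])
    vectors = []
    for i in range(n):
        ptm_flags: dict[str, Optional[bool]] = {}
        for name in PTM_FEATURES:
            if rng.random() < config.ptm_missing_prob:
                ptm_flags[name] = None
            else:
                ptm_flags[name] = bool(truth[name][i])
        nterm: Optional[bool] = bool(truth[bn.N_TERM][i])
        if rng.random() < config.n_term_unknown_prob:
            nterm = None
        vectors.append(
            FeatureVector(
                protein_id=f"p{i:04d}",
                n_term_stabilizing=nterm,
                ptm_flags=ptm_flags,
                domain_flags={k: bool(truth[k][i]) for k in DOMAIN_FEATURES},
                disorder_flags={k: bool(truth[k][i]) for k in DISORDER_FEATURES},
                pwm_scores={
                    kind: float(truth[leaf][i]) for kind, leaf in bn.PWM_LEAVES.items()
                },
                svm_score=float(truth[bn.SVM_LEAF][i]) if bn.SVM_LEAF in truth else None,
                label="stable" if truth[bn.STABILITY][i] == 1 else "unstable",
            )
        )
    return vectors


def simulate_bn_records(
    config: FixtureConfig,
    seed: int,
    spec: Optional[bn.NetworkSpec] = None,
    params: Optional[bn.Parameters] = None,
) -> tuple[list[FeatureVector], dict[str, np.ndarray]]:
    """Network samples with the benchmark's per-class counts.

    Ancestral draws are kept until ``n_stable`` stable and ``n_unstable``
    unstable records have been collected (the benchmark, like the study it
    emulates, fixes the class mix; use :func:`simulate_ancestral_records`
    when the untilted joint is needed). Returns the feature vectors
    (continuous leaves as scores, stability as the label) together with
    the raw sampled node values, including the latent summary nodes, for
    tests that need the planted truth. PTM flags are hidden ("unknown")
    with probability ``ptm_missing_prob`` to emulate silent annotation
    sources; the hidden truth stays in the returned sample table.
    """
    if spec is None or params is None:
        spec, params = default_ground_truth()
    rng = np.random.default_rng(seed)
    needed = {1: config.n_stable, 0: config.n_unstable}
    kept: dict[str, list] = {n.name: [] for n in spec.nodes}
    have = {0: 0, 1: 0}
    guard = 0
    while (have[0] < needed[0] or have[1] < needed[1]) and guard < 200:
        guard += 1
        batch = max(512, 2 * (needed[0] - have[0] + needed[1] - have[1]))
        sample = bn.sample_records(spec, params, batch, rng)
        for i in range(batch):
            cls = int(sample[bn.STABILITY][i])
            if have[cls] < needed[cls]:
                for name in kept:
                    kept[name].append(sample[name][i])
                have[cls] += 1
    if have[0] < needed[0] or have[1] < needed[1]:
        raise RuntimeError("could not reach requested class counts")
    truth = {name: np.array(vals) for name, vals in kept.items()}
    return _truth_to_vectors(config, truth, rng), truth


def simulate_ancestral_records(
    config: FixtureConfig,
    n: int,
    seed: int,
    spec: Optional[bn.NetworkSpec] = None,
    params: Optional[bn.Parameters] = None,
) -> tuple[list[FeatureVector], dict[str, np.ndarray]]:
    """Plain ancestral samples (no class balancing).

    This is the generator to use for parameter-recovery studies: the
    empirical distribution is exactly the network's joint.
    """
    if spec is None or params is None:
        spec, params = default_ground_truth()
    rng = np.random.default_rng(seed)
    truth = bn.sample_records(spec, params, n, rng)
    return _truth_to_vectors(config, truth, rng), truth


# ---------------------------------------------------------------------------
# Motifs and sequences


def simulate_motif_windows(
    config: FixtureConfig, seed: int
) -> dict[str, dict[str, list[str]]]:
    """Synthetic foreground window sets for the two phosphosite PWM kinds.

    Each motif fixes a central acceptor residue (Y, or S/T) plus two
    conserved flanking positions; the remaining positions draw from the
    background composition.
    """
    rng = np.random.default_rng(seed)
    base = _composition_vector({})
    out: dict[str, dict[str, list[str]]] = {}
    center = config.motif_width // 2
    for kind in PWM_KINDS:
        acceptors = "Y" if kind == "tyrosine" else "ST"
        motifs: dict[str, list[str]] = {}
        for m in range(config.n_motifs_per_kind):
            flank_pos = rng.choice(
                [p for p in range(config.motif_width) if p != center],
                size=2,
                replace=False,
            )
            flank_res = rng.choice(list(AMINO_ACIDS), size=2)
            windows = []
            for _ in range(config.windows_per_motif):
                window = list(
                    rng.choice(list(AMINO_ACIDS), size=config.motif_width, p=base)
                )
                window[center] = acceptors[rng.integers(len(acceptors))]
                for p, r in zip(flank_pos, flank_res):
                    window[p] = r
                windows.append("".join(window))
            motifs[f"{kind}_motif{m}"] = windows
        out[kind] = motifs
    return out


def simulate_sequences(
    config: FixtureConfig,
    vectors: Sequence[FeatureVector],
    motif_windows: dict[str, dict[str, list[str]]],
    seed: int,
) -> tuple[dict[str, str], dict[str, Optional[int]], dict[str, dict[str, int]]]:
    """Sequences consistent with each record's planted features.

    Residues draw from the class composition profile; the N-terminal
    residue honours the record's degron flag through the Met-removal rule
    (a destabilizing flag plants an R/K/H/F/L/W/I/Y mature terminus, a
    stabilizing one either keeps Met or exposes a small second residue);
    signal-peptide records get a cleavage position whose downstream
    residue carries the flag instead. Phospho motif windows are planted
    with the class-specific probability at uniform positions. Returns
    (sequences, cleavage positions, planted motif offsets).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    cleavages: dict[str, Optional[int]] = {}
    planted: dict[str, dict[str, int]] = {}
    aa = np.array(list(AMINO_ACIDS))
    for v in vectors:
        label = v.label or "unstable"
        profile = config.class_composition(label)
        length = int(
            np.clip(
                rng.lognormal(config.seq_len_log_mean, config.seq_len_log_sigma),
                config.seq_len_min,
                config.seq_len_max,
            )
        )
        seq = list(rng.choice(aa, size=length, p=profile))

        has_signal = v.domain_flags.get("signal_peptide", False)
        cleavage: Optional[int] = None
        if has_signal:
            cleavage = int(rng.integers(15, 31))  # 1-based last signal residue
            terminus_idx = cleavage  # 0-based index of the mature N-terminus
            seq[0] = "M"
        else:
            terminus_idx = 0
        if v.n_term_stabilizing is None:
            seq[terminus_idx] = "X"
        elif v.n_term_stabilizing:
            if not has_signal and rng.random() < 0.5:
                seq[0] = "M"
                seq[1] = rng.choice(sorted(MET_REMOVAL_SECOND))
            else:
                seq[terminus_idx] = rng.choice(STABILIZING_RESIDUES)
                if terminus_idx == 0 and seq[0] == "M" and seq[1] in MET_REMOVAL_SECOND:
                    seq[1] = "E"  # keep Met exposed: avoid accidental removal
        else:
            choices = sorted(DESTABILIZING_RESIDUES)
            seq[terminus_idx] = rng.choice(choices)

        offsets: dict[str, int] = {}
        for kind in PWM_KINDS:
            prob = config.motif_plant_prob.get(label, 0.0)
            if rng.random() < prob:
                motif_id = rng.choice(sorted(motif_windows[kind]))
                window = motif_windows[kind][motif_id][
                    rng.integers(len(motif_windows[kind][motif_id]))
                ]
                lo = max(2, (cleavage or 0) + 1)
                hi = length - len(window)
                if hi <= lo:
                    continue  # sequence too short to plant; skip
                pos = int(rng.integers(lo, hi))
                seq[pos : pos + len(window)] = list(window)
                offsets[kind] = pos
        sequences[v.protein_id] = "".join(seq)
        cleavages[v.protein_id] = cleavage
        planted[v.protein_id] = offsets
    return sequences, cleavages, planted


# ---------------------------------------------------------------------------
# Full dataset


@dataclass
class SyntheticDataset:
    config: FixtureConfig
    seed: int
    vectors: list[FeatureVector]
    truth: dict[str, np.ndarray]
    sequences: dict[str, str]
    annotations: list[AnnotationRecord]
    labels: dict[str, str]
    motif_windows: dict[str, dict[str, list[str]]]
    planted_offsets: dict[str, dict[str, int]]
    gpsp_records: list[GpspRecord]
    gpsp_labels: list[str]


def simulate_dataset(
    config: Optional[FixtureConfig] = None, seed: int = 0
) -> SyntheticDataset:
    """Generate the complete, mutually consistent set of pipeline inputs."""
    config = config or FixtureConfig()
    vectors, truth = simulate_bn_records(config, seed)
    motif_windows = simulate_motif_windows(config, seed + 1)
    sequences, cleavages, planted = simulate_sequences(
        config, vectors, motif_windows, seed + 2
    )
    rng = np.random.default_rng(seed + 3)
    annotations = []
    for v in vectors:
        fractions = {}
        for flag, dtype in (
            ("disorder_loops_coils_80", "loops_coils"),
            ("disorder_hot_loops_80", "hot_loops"),
        ):
            if v.disorder_flags[flag]:
                fractions[dtype] = float(rng.uniform(0.801, 1.0))
            else:
                fractions[dtype] = float(rng.uniform(0.0, 0.8))
        fractions["rem465"] = float(rng.uniform(0.0, 0.6))
        annotations.append(
            AnnotationRecord(
                protein_id=v.protein_id,
                ptm_flags=dict(v.ptm_flags),
                domain_flags=dict(v.domain_flags),
                disorder_fractions=fractions,
                signal_cleavage_pos=cleavages[v.protein_id],
            )
        )
    labels = {v.protein_id: v.label for v in vectors}
    gpsp_records, gpsp_labels = simulate_gpsp(config, seed + 4)
    return SyntheticDataset(
        config=config,
        seed=seed,
        vectors=vectors,
        truth=truth,
        sequences=sequences,
        annotations=annotations,
        labels=labels,
        motif_windows=motif_windows,
        planted_offsets=planted,
        gpsp_records=gpsp_records,
        gpsp_labels=gpsp_labels,
    )
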