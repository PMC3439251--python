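"""Motif-anchored position-weight matrices for phosphosite scoring.

Each matrix is built from a foreground set of equal-length sequence windows
(known phosphorylation sites matching one motif). A cell holds
``log((F + P) / BG)`` where ``F`` is the foreground frequency of the
residue at that position, ``BG`` its background frequency and ``P = BG/10``
a pseudocount that keeps every cell finite. A window's match score is the
sum of its per-position cells and a sequence is scored by the maximum over
all matrices and all ungapped window placements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_RESIDUES

PSEUDOCOUNT_DIVISOR = 10.0


@dataclass
class PwmModel:
    motif_id: str
    cells: np.ndarray  # (width, 20) log-ratio scores
    background: np.ndarray  # (20,) frequencies summing to 1
    n_foreground: int

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.cells.ndim != 2 or self.cells.shape[1] != N_RESIDUES:
            raise ValueError("cells must be a (width, 20) matrix")
        if not np.all(np.isfinite(self.cells)):
            raise ValueError("PWM cells must be finite")

    @property
    def width(self) -> int:
        return self.cells.shape[0]


@dataclass
class PwmSet:
    kind: str  # "tyrosine" or "ser_thr"
    models: list[PwmModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("a PWM set must contain at least one model")


def build_pwm(
    motif_id: str,
    foreground_windows: Sequence[str],
    background: np.ndarray,
) -> PwmModel:
    """Estimate a PWM from foreground windows against a background.

    ``F`` is the column-wise residue frequency over the windows, so
    duplicated windows leave the matrix unchanged; the pseudocount is
    ``BG/10`` per residue.
    """
    if not foreground_windows:
        raise ValueError("at least one foreground window required")
    width = len(foreground_windows[0])
    if any(len(w) != width for w in foreground_windows):
        raise ValueError("foreground windows must all have the same length")
    background = np.asarray(background, dtype=float)
    if background.shape != (N_RESIDUES,) or np.any(background <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    background = background / background.sum()

    counts = np.zeros((width, N_RESIDUES))
    for window in foreground_windows:
        for pos, residue in enumerate(window.upper()):
            if residue not in AA_INDEX:
                raise ValueError(f"non-standard residue {residue!r} in window")
            counts[pos, AA_INDEX[residue]] += 1
    freq = counts / len(foreground_windows)
    pseudo = background / PSEUDOCOUNT_DIVISOR
    cells = np.log((freq + pseudo[None, :]) / background[None, :])
    return PwmModel(
        motif_id=motif_id,
        cells=cells,
        background=background,
        n_foreground=len(foreground_windows),
    )


def window_score(model: PwmModel, window: str) -> Optional[float]:
    """Score one window; ``None`` if it contains a non-standard residue."""
    if len(window) != model.width:
        raise ValueError("window length does not match model width")
    total = 0.0
    for pos, residue in enumerate(window.upper()):
        idx = AA_INDEX.get(residue)
        if idx is None:
            return None
        total += model.cells[pos, idx]
    return total


def scan_sequence(sequence: str, pwms: PwmSet) -> Optional[float]:
    """Maximum match score of any matrix at any ungapped offset.

    Windows containing non-standard residues are skipped; if no matrix fits
    anywhere in the sequence (or every window is skipped) the sentinel
    ``None`` is returned and the caller treats the score as absent.
    """
    seq = sequence.upper()
    idx = np.array([AA_INDEX.get(r, -1) for r in seq], dtype=int)
    best: Optional[float] = None
    for model in pwms.models:
        w = model.width
        if len(seq) < w:
            continue
        n_win = len(seq) - w + 1
        # (n_win, w) matrix of residue indices for every offset
        offsets = np.arange(n_win)[:, None] + np.arange(w)[None, :]
        win_idx = idx[offsets]
        valid = np.all(win_idx >= 0, axis=1)
        if not np.any(valid):
            continue
        scores = model.cells[np.arange(w)[None, :], win_idx[valid]].sum(axis=1)
        top = float(scores.max())
        if best is None or top > best:
            best = top
    return best


# ---------------------------------------------------------------------------
# Serialization


def pwm_set_to_dict(pwms: PwmSet) -> dict:
    return {
        "kind": pwms.kind,
        "alphabet": AMINO_ACIDS,
        "models": [
            {
                "motif_id": m.motif_id,
                "width": m.width,
                "cells": m.cells.tolist(),
                "background": m.background.tolist(),
                "n_foreground": m.n_foreground,
            }
            for m in pwms.models
        ],
    }


def pwm_set_from_dict(doc: dict) -> PwmSet:
    models = [
        PwmModel(
            motif_id=m["motif_id"],
            cells=np.array(m["cells"]),
            background=np.array(m["background"]),
            n_foreground=int(m["n_foreground"]),
        )
        for m in doc["models"]
    ]
    return PwmSet(kind=doc["kind"], models=models)


def save_pwm_sets(pwm_sets: dict[str, PwmSet], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: pwm_set_to_dict(v) for k, v in pwm_sets.items()}, fh, indent=1)


def load_pwm_sets(path) -> dict[str, PwmSet]:
    with open(path) as fh:
        doc = json.load(fh)
    return {k: pwm_set_from_dict(v) for k, v in doc.items()}


def read_foreground_windows(path) -> list[str]:
    """Read motif foreground windows, one per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def background_from_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Residue frequencies over a collection of sequences (the proteome)."""
    counts = np.zeros(N_RESIDUES)
    for seq in sequences:
        for residue in seq.upper():
            idx = AA_INDEX.get(residue)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("no standard residues in background sequences")
    # floor so that rare residues never zero out the pseudocount
    freq = counts / counts.sum()
    freq = np.maximum(freq, 1e-4)
    return freq / freq.sum()
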