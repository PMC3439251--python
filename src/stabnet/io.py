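"""Readers and writers for the external artifacts of the stability pipeline.

Tabular formats are TSV with a header row; sequences travel as FASTA;
run configuration as YAML; trained models as JSON documents (see the
``pwm``, ``svm`` and ``bn`` modules for the model schemas).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import DOMAIN_FEATURES, DISORDER_TYPES, PTM_FEATURES

N_BINS = 7
#: how far off 1.0 a row's bin sum may be before it is rejected outright
#: (proportions rounded to two decimals can drift by a few percent)
BIN_SUM_TOLERANCE = 5e-2

CLASS_LABELS = ("stable", "unstable", "non-assigned")


@dataclass
class GpspRecord:
    """One protein's normalized distribution over the 7 FACS stability bins.

    ``bins[i]`` is the proportion of cells observed in bin R(i+1); the bins
    are renormalized to sum to one on load (microarray-derived proportions
    carry rounding noise).
    """

    protein_id: str
    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(
                f"{self.protein_id}: expected {N_BINS} bins, got {self.bins.shape}"
            )
        if np.any(self.bins < 0):
            raise ValueError(f"{self.protein_id}: negative bin weight")
        total = float(self.bins.sum())
        if total <= 0:
            raise ValueError(f"{self.protein_id}: bin weights sum to zero")
        if abs(total - 1.0) > BIN_SUM_TOLERANCE:
            raise ValueError(
                f"{self.protein_id}: bin weights sum to {total:.4f}, "
                f"outside tolerance {BIN_SUM_TOLERANCE}"
            )
        self.bins = self.bins / total


@dataclass
class AnnotationRecord:
    """Per-protein annotation flags consumed by the feature builder.

    PTM flags are tri-state: ``True``/``False``/``None`` where ``None``
    means the annotation source is silent (absence of an annotation is not
    evidence of absence). Domain flags are strict Booleans. Disorder
    fractions are the fraction of the sequence predicted disordered under
    each of the three disorder definitions. ``signal_cleavage_pos`` is the
    1-based index of the LAST residue of the signal peptide; the mature
    chain starts at ``signal_cleavage_pos + 1``.
    """

    protein_id: str
    ptm_flags: dict[str, Optional[bool]] = field(default_factory=dict)
    domain_flags: dict[str, bool] = field(default_factory=dict)
    disorder_fractions: dict[str, float] = field(default_factory=dict)
    signal_cleavage_pos: Optional[int] = None

    def __post_init__(self) -> None:
        for name, frac in self.disorder_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(
                    f"{self.protein_id}: disorder fraction {name}={frac} outside [0, 1]"
                )
        if self.signal_cleavage_pos is not None and self.signal_cleavage_pos < 1:
            raise ValueError(
                f"{self.protein_id}: signal cleavage position must be >= 1"
            )


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    seed: int = 0
    cv_folds: int = 10
    cv_repeats: int = 5
    model_variant: str = "bn_svm"
    unstable_lt: float = 0.2
    stable_gt: float = 0.75
    em_max_iter: int = 200
    em_tol: float = 1e-6
    em_pseudocount: float = 1.0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.unstable_lt < self.stable_gt <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 <= unstable_lt < stable_gt <= 1"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# GPSP bin tables


def read_gpsp_table(path) -> list[GpspRecord]:
    """Read a TSV of id + 7 bin-weight columns into :class:`GpspRecord` rows."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != N_BINS + 1:
        raise ValueError(
            f"expected 7 bins (1 id column + 7 numeric columns), "
            f"got {df.shape[1] - 1} numeric columns"
        )
    records = []
    for _, row in df.iterrows():
        pid = str(row.iloc[0])
        bins = row.iloc[1:].to_numpy(dtype=float)
        try:
            records.append(GpspRecord(pid, bins))
        except ValueError as exc:
            raise ValueError(f"bad GPSP row for {pid!r}: {exc}") from exc
    return records


def write_gpsp_table(records: Sequence[GpspRecord], path) -> None:
    cols = {"protein_id": [r.protein_id for r in records]}
    for i in range(N_BINS):
        cols[f"R{i + 1}"] = [r.bins[i] for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# Annotation tables

_DISORDER_COLUMNS = {name: f"disorder_{name}" for name in DISORDER_TYPES}

ANNOTATION_COLUMNS = (
    ["protein_id"]
    + list(PTM_FEATURES)
    + list(DOMAIN_FEATURES)
    + list(_DISORDER_COLUMNS.values())
    + ["signal_cleavage_pos"]
)


def _parse_tristate(value) -> Optional[bool]:
    if pd.isna(value) or str(value).upper() == "NA":
        return None
    return bool(int(value))


def read_annotations(path) -> list[AnnotationRecord]:
    """Read the per-protein annotation TSV (PTMs, domains, disorder, cleavage)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
    if unknown:
        raise ValueError(
            f"unknown annotation columns {sorted(unknown)}; "
            f"accepted schema: {ANNOTATION_COLUMNS}"
        )
    missing = {"protein_id", *PTM_FEATURES, *DOMAIN_FEATURES} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        ptm = {name: _parse_tristate(row[name]) for name in PTM_FEATURES}
        dom = {name: bool(int(row[name])) for name in DOMAIN_FEATURES}
        dis = {
            name: float(row[col])
            for name, col in _DISORDER_COLUMNS.items()
            if col in df.columns and not pd.isna(row[col])
        }
        cleave = None
        if "signal_cleavage_pos" in df.columns and not pd.isna(
            row["signal_cleavage_pos"]
        ):
            cleave = int(row["signal_cleavage_pos"])
        records.append(
            AnnotationRecord(
                protein_id=str(row["protein_id"]),
                ptm_flags=ptm,
                domain_flags=dom,
                disorder_fractions=dis,
                signal_cleavage_pos=cleave,
            )
        )
    return records


def write_annotations(records: Sequence[AnnotationRecord], path) -> None:
    def tri(v):
        return "NA" if v is None else int(v)

    rows = []
    for r in records:
        row = {"protein_id": r.protein_id}
        row.update({name: tri(r.ptm_flags.get(name)) for name in PTM_FEATURES})
        row.update({name: int(r.domain_flags.get(name, False)) for name in DOMAIN_FEATURES})
        for name, col in _DISORDER_COLUMNS.items():
            row[col] = r.disorder_fractions.get(name, 0.0)
        row["signal_cleavage_pos"] = (
            "NA" if r.signal_cleavage_pos is None else r.signal_cleavage_pos
        )
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequences


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Predictions


def write_predictions(records, path) -> None:
    """Write (protein_id, score, class_label) triples as a predictions TSV.

    Scores must be probabilities in [0, 1]; rows are written in input order.
    """
    rows = []
    for pid, score, label in records:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"{pid}: score {score} outside [0, 1]")
        if label not in CLASS_LABELS:
            raise ValueError(f"{pid}: unknown class label {label!r}")
        rows.append({"protein_id": pid, "score": f"{score:.6f}", "class": label})
    pd.DataFrame(rows, columns=["protein_id", "score", "class"]).to_csv(
        path, sep="\t", index=False
    )


def read_predictions(path) -> list[tuple[str, float, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        (str(r["protein_id"]), float(r["score"]), str(r["class"]))
        for _, r in df.iterrows()
    ]
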