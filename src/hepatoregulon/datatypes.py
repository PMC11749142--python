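"""Core in-memory containers shared by all pipeline stages.

The central objects are thin dataclass wrappers around pandas structures:
an :class:`ExpressionMatrix` (genes x samples with a stage label per
sample), regulons (a transcription factor plus its inferred activating
targets), an :class:`ActivityMatrix` (regulon x sample rank-AUC scores),
and the chromatin-accessibility side (peak intervals with sequence, and
position weight matrices for TF binding motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented constraint."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with per-sample stage labels.

    ``values`` holds nonnegative expression (raw counts, normalized counts,
    or log-scale if ``log_transformed``); ``stage_of`` maps every sample ID
    to its developmental-stage label; ``stage_order`` fixes the ordering of
    stages along the trajectory (e.g. mature -> progenitor -> re-differentiated).
    """

    values: pd.DataFrame
    stage_of: pd.Series
    stage_order: list[str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.stage_of = pd.Series(self.stage_of)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        missing = [s for s in self.values.columns if s not in self.stage_of.index]
        if missing:
            raise ValueError(f"samples without a stage label: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        unknown = set(self.stage_of[list(self.values.columns)]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"stages missing from stage_order: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of[s] == stage]

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean expression (genes x stages, in stage_order)."""
        cols = {st: self.values[self.samples_of_stage(st)].mean(axis=1) for st in self.stage_order}
        return pd.DataFrame(cols)[self.stage_order]

    def log_values(self) -> pd.DataFrame:
        """Expression on log2 scale (log2(x+1) applied unless already log)."""
        if self.log_transformed:
            return self.values
        return np.log2(self.values + 1.0)


@dataclass
class Regulon:
    """A transcription factor and its inferred activating target genes.

    ``link_scores`` maps each target to the co-expression score that put it
    in the regulon; after motif pruning, ``supported`` marks that every
    remaining target has a motif-bearing accessible promoter peak.
    """

    tf: str
    link_scores: dict[str, float]
    supported: bool = False

    def __post_init__(self) -> None:
        if self.tf in self.link_scores:
            raise ValueError(f"regulon for {self.tf} lists the TF as its own target")

    @property
    def targets(self) -> set[str]:
        return set(self.link_scores)

    @property
    def size(self) -> int:
        return len(self.link_scores)

    @property
    def name(self) -> str:
        return self.tf


# a candidate regulon (pre motif pruning) has the same shape
CandidateRegulon = Regulon


@dataclass
class ActivityMatrix:
    """Regulon x sample rank-AUC activities in [0, 1]."""

    values: pd.DataFrame
    stage_of: pd.Series
    stage_order: list[str]
    top_fraction: float
    tie_seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError("activities must lie in [0, 1]")

    @property
    def regulons(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.stage_of[s] == stage]

    def stage_means(self) -> pd.DataFrame:
        cols = {st: self.values[self.samples_of_stage(st)].mean(axis=1) for st in self.stage_order}
        return pd.DataFrame(cols)[self.stage_order]


def peak_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class PeakSet:
    """Accessible-peak intervals with sequence.

    ``intervals`` has columns (chrom, start, end, stage) in 0-based
    half-open BED convention; the same genomic window may be accessible in
    several stages (one row per stage). ``sequences`` maps the peak ID
    ``chrom:start-end`` to its DNA string.
    """

    intervals: pd.DataFrame
    sequences: dict[str, str]
    width: int = 500

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "stage"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"peak intervals need columns {sorted(required)}")
        widths = self.intervals["end"] - self.intervals["start"]
        if len(widths) and not (widths == self.width).all():
            bad = self.intervals[widths != self.width]
            raise ValueError(
                f"peak width mismatch (expected {self.width}): "
                f"{bad.iloc[0]['chrom']}:{bad.iloc[0]['start']}-{bad.iloc[0]['end']}"
            )
        for pid, seq in self.sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"peak {pid} has non-ACGTN characters")

    def _ids(self, frame: pd.DataFrame) -> list[str]:
        return [
            peak_id(c, s, e)
            for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
        ]

    @property
    def peak_ids(self) -> list[str]:
        return list(dict.fromkeys(self._ids(self.intervals)))

    def peaks_of_stage(self, stage: str) -> set[str]:
        return set(self._ids(self.intervals[self.intervals["stage"] == stage]))

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["stage"]))

    def unique_intervals(self) -> pd.DataFrame:
        return self.intervals.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)


@dataclass
class MotifPWM:
    """Position weight matrix for one TF's binding motif.

    ``matrix`` is position x base (A, C, G, T) probabilities after
    pseudocount regularization; ``background`` the base composition the
    log-odds are computed against.
    """

    tf: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError(f"motif {self.tf}: matrix must be positions x 4 bases")
        mat = mat + self.pseudocount
        sums = mat.sum(axis=1, keepdims=True)
        if np.abs(sums - 1.0).max() > 1e-12:  # already-normalized rows pass through bit-identically
            mat = mat / sums
        self.matrix = mat
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError(f"motif {self.tf}: background must sum to 1")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"motif {self.tf}: rows must sum to 1 after normalization")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class GeneSet:
    """A named set of gene IDs (marker signature, stemness panel, ...)."""

    name: str
    genes: set[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ReferencePanel:
    """Gene x reference-stage mean profiles along a developmental gradient."""

    profiles: pd.DataFrame
    stage_labels: list[str]

    def __post_init__(self) -> None:
        if list(self.profiles.columns) != list(self.stage_labels):
            raise ValueError("panel columns must match stage_labels in order")
        if not np.isfinite(self.profiles.to_numpy(dtype=float)).all():
            raise ValueError("reference panel contains non-finite values")


@dataclass
class GroundTruth:
    """Planted regulon structure of a simulated dataset (the test oracle)."""

    regulons: dict[str, set[str]]
    activity_profile: pd.DataFrame  # TF x stage, nonnegative
    differential_tfs_up: set[str]  # progenitor-up at the middle stage
    differential_tfs_down: set[str]  # mature-up (dips at the middle stage)
    hepatocyte_program_tf: str = ""
    cholangiocyte_program_tf: str = ""

    def __post_init__(self) -> None:
        tfs = set(self.regulons)
        for tf, targets in self.regulons.items():
            overlap = tfs & set(targets)
            if overlap:
                raise ValueError(f"targets of {tf} overlap the TF set: {sorted(overlap)}")
        prof = self.activity_profile
        for tf in self.differential_tfs_up | self.differential_tfs_down:
            row = prof.loc[tf]
            if row.nunique() <= 1:
                raise ValueError(f"differential TF {tf} has a constant activity row")
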