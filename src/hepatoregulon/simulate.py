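"""Synthetic staged-organoid datasets with planted regulon structure.

The generator emulates the three-stage organoid trajectory (mature solid ->
hollow progenitor -> re-differentiated hepatobiliary) at bulk-RNA scale:
every planted transcription factor drives a disjoint target set whose
expression is multiplicatively induced wherever the TF is active, and every
target promoter carries an accessible peak with an embedded instance of the
TF's binding motif in exactly the stages where the TF is active. The planted
structure is returned as a :class:`~hepatoregulon.datatypes.GroundTruth`
object so downstream inference can be scored against a known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DNA_ALPHABET,
    ConfigurationError,
    ExpressionMatrix,
    GeneSet,
    GroundTruth,
    MotifPWM,
    PeakSet,
    ReferencePanel,
    peak_id,
)

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("SHO", "HHO", "HBO")

# genomic layout of the toy genome: one gene every GENE_SPACING bp on chr1,
# background peaks on a separate contig so they can never be promoter-assigned
GENE_SPACING = 25_000
FIRST_TSS = 10_000
BACKGROUND_CHROM = "chrBG"


def default_activity_profile(
    tf_names: list[str],
    stages: tuple[str, ...] = DEFAULT_STAGES,
    n_progenitor_up: int = 2,
    n_mature_up: int = 2,
) -> pd.DataFrame:
    """Stage-activity design mirroring the organoid study layout.

    The first ``n_progenitor_up`` TFs are active only at the middle
    (progenitor) stage, the next ``n_mature_up`` only at the flanking mature
    stages, and the remainder are constitutively active (present regulons
    with no differential signal).
    """
    if len(stages) < 3:
        raise ConfigurationError("stages: need at least 3 stages for the up/down design")
    if n_progenitor_up + n_mature_up > len(tf_names):
        raise ConfigurationError("n_tfs: fewer TFs than planted differential roles")
    mid = len(stages) // 2
    prof = pd.DataFrame(1.0, index=tf_names, columns=list(stages))
    for i, tf in enumerate(tf_names):
        if i < n_progenitor_up:
            prof.loc[tf] = 0.0
            prof.loc[tf, stages[mid]] = 1.0
        elif i < n_progenitor_up + n_mature_up:
            prof.loc[tf] = 1.0
            prof.loc[tf, stages[mid]] = 0.0
    return prof


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    The defaults are the study-scale conditions used throughout the test
    suite: 200 genes, 10 TFs with 15 targets each, 3 stages x 3 replicates,
    a 2x induction per unit TF activity, and log-normal noise with sd 0.2
    on the natural-log scale.
    """

    n_genes: int = 200
    n_tfs: int = 10
    targets_per_regulon: int = 15
    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 3
    activity_profile: pd.DataFrame | None = None
    n_progenitor_up: int = 2
    n_mature_up: int = 2
    effect_size: float = 2.0
    noise_sd: float = 0.2
    peak_width: int = 500
    motif_length: int = 8
    background_peaks: int = 40
    dominant_base_prob: float = 0.9
    score_threshold_fraction: float = 0.8
    baseline_log10_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    tf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_tfs < 1:
            raise ConfigurationError("n_tfs: must be >= 1")
        if self.targets_per_regulon < 1:
            raise ConfigurationError("targets_per_regulon: must be >= 1")
        if self.n_tfs * self.targets_per_regulon > self.n_genes - self.n_tfs:
            raise ConfigurationError(
                "n_genes: need n_tfs * targets_per_regulon <= n_genes - n_tfs "
                f"({self.n_tfs} * {self.targets_per_regulon} > {self.n_genes} - {self.n_tfs})"
            )
        if self.peak_width <= self.motif_length:
            raise ConfigurationError("peak_width: must exceed motif_length")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if self.effect_size <= 0:
            raise ConfigurationError("effect_size: must be > 0")
        if self.reps_per_stage < 1:
            raise ConfigurationError("reps_per_stage: must be >= 1")
        if len(self.stages) < 2:
            raise ConfigurationError("stages: need at least 2 stages")
        self.tf_names = [f"TF{i + 1:02d}" for i in range(self.n_tfs)]
        if self.activity_profile is None:
            self.activity_profile = default_activity_profile(
                self.tf_names, self.stages, self.n_progenitor_up, self.n_mature_up
            )
        prof = self.activity_profile
        if list(prof.index) != self.tf_names or list(prof.columns) != list(self.stages):
            raise ConfigurationError("activity_profile: index/columns must match TF names and stages")
        if (prof.to_numpy() < 0).any():
            raise ConfigurationError("activity_profile: activities must be nonnegative")


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    expression: ExpressionMatrix
    peaks: PeakSet
    motifs: dict[str, MotifPWM]
    signatures: dict[str, GeneSet]
    panel: ReferencePanel
    truth: GroundTruth
    tss_table: pd.DataFrame  # gene -> (chrom, tss)
    config: SimConfig


def _sample_motif_matrix(rng: np.random.Generator, length: int, dominant: float) -> np.ndarray:
    """Random PWM with one dominant base per position."""
    mat = np.full((length, 4), (1.0 - dominant) / 3.0)
    picks = rng.integers(0, 4, size=length)
    mat[np.arange(length), picks] = dominant
    return mat


def _sample_motif_instance(rng: np.random.Generator, pwm: MotifPWM, threshold: float) -> str:
    """Draw a motif instance base-by-base from the PWM, rejecting draws that
    the scanner itself would miss at ``threshold``; falls back to the
    consensus so the planted-support invariant always holds."""
    lo = pwm.log_odds
    for _ in range(100):
        idx = np.array([rng.choice(4, p=row) for row in pwm.matrix])
        score = lo[np.arange(len(pwm)), idx].sum()
        if score >= threshold:
            return "".join(DNA_ALPHABET[i] for i in idx)
    return pwm.consensus


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate expression, peaks, motifs, signatures, a reference panel and
    the planted ground truth, all reproducible from ``config.seed``.

    Expression of a target gene g of TF t in sample s is
    ``baseline_g * effect_size ** activity(t, stage(s)) * exp(noise)``;
    the TF's own expression tracks its activity the same way, and genes
    outside any regulon are pure baseline noise. Each target promoter gets
    one fixed-width peak that is emitted in a stage's accessible set iff the
    TF is active there and that carries at least one sampled instance of the
    TF's motif. Background peaks carry random sequence and are accessible in
    every stage.
    """
    rng = np.random.default_rng(config.seed)
    prof = config.activity_profile
    tf_names = config.tf_names

    n_targets = config.n_tfs * config.targets_per_regulon
    target_names = [f"G{i + 1:03d}" for i in range(n_targets)]
    n_bg_genes = config.n_genes - config.n_tfs - n_targets
    bg_names = [f"B{i + 1:03d}" for i in range(n_bg_genes)]
    genes = tf_names + target_names + bg_names

    regulons = {
        tf: set(target_names[i * config.targets_per_regulon : (i + 1) * config.targets_per_regulon])
        for i, tf in enumerate(tf_names)
    }
    regulator_of = {g: tf for tf, targets in regulons.items() for g in targets}

    samples = [f"{st}_r{r + 1}" for st in config.stages for r in range(config.reps_per_stage)]
    stage_of = pd.Series({s: s.rsplit("_r", 1)[0] for s in samples})

    lo, hi = config.baseline_log10_range
    baselines = pd.Series(10.0 ** rng.uniform(lo, hi, size=len(genes)), index=genes)

    activity_of_gene = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        tf = g if g in regulons else regulator_of.get(g)
        if tf is None:
            continue
        for si, s in enumerate(samples):
            activity_of_gene[gi, si] = prof.loc[tf, stage_of[s]]
    noise = rng.normal(0.0, config.noise_sd, size=activity_of_gene.shape) if config.noise_sd > 0 else 0.0
    values = (
        baselines.to_numpy()[:, None]
        * config.effect_size ** activity_of_gene
        * np.exp(noise)
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        stage_of=stage_of,
        stage_order=list(config.stages),
    )

    # toy genome: every gene gets a TSS on chr1; target promoters get peaks
    tss_table = pd.DataFrame(
        {"chrom": "chr1", "tss": [FIRST_TSS + i * GENE_SPACING for i in range(len(genes))]},
        index=genes,
    )

    motifs = {
        tf: MotifPWM(tf=tf, matrix=_sample_motif_matrix(rng, config.motif_length, config.dominant_base_prob))
        for tf in tf_names
    }

    rows: list[dict] = []
    sequences: dict[str, str] = {}
    half = config.peak_width // 2
    for g in target_names:
        tf = regulator_of[g]
        tss = int(tss_table.loc[g, "tss"])
        start, end = tss - half, tss - half + config.peak_width
        pid = peak_id("chr1", start, end)
        seq = "".join(rng.choice(list(DNA_ALPHABET), size=config.peak_width))
        pwm = motifs[tf]
        instance = _sample_motif_instance(
            rng, pwm, config.score_threshold_fraction * pwm.max_score
        )
        offset = int(rng.integers(0, config.peak_width - config.motif_length + 1))
        seq = seq[:offset] + instance + seq[offset + config.motif_length :]
        sequences[pid] = seq
        for st in config.stages:
            if prof.loc[tf, st] > 0:
                rows.append({"chrom": "chr1", "start": start, "end": end, "stage": st})
    for j in range(config.background_peaks):
        start = 1_000 + j * (config.peak_width + 1_000)
        end = start + config.peak_width
        pid = peak_id(BACKGROUND_CHROM, start, end)
        sequences[pid] = "".join(rng.choice(list(DNA_ALPHABET), size=config.peak_width))
        for st in config.stages:
            rows.append({"chrom": BACKGROUND_CHROM, "start": start, "end": end, "stage": st})
    peaks = PeakSet(intervals=pd.DataFrame(rows), sequences=sequences, width=config.peak_width)

    # marker programs: one progenitor-stage TF plays the cholangiocyte role
    # (its targets peak where the biliary-competent progenitors live), one
    # mature-stage TF the hepatocyte role; stemness = all progenitor targets
    mid = len(config.stages) // 2
    mid_stage = config.stages[mid]
    up_tfs = {tf for tf in tf_names if prof.loc[tf, mid_stage] > prof.loc[tf].drop(mid_stage).max()}
    down_tfs = {tf for tf in tf_names if prof.loc[tf, mid_stage] < prof.loc[tf].drop(mid_stage).min()}
    chol_tf = min(up_tfs) if up_tfs else ""
    hep_tf = min(down_tfs) if down_tfs else ""
    signatures: dict[str, GeneSet] = {}
    if hep_tf:
        signatures["hepatocyte_signature"] = GeneSet(
            "hepatocyte_signature", regulons[hep_tf], source="planted mature program"
        )
    if chol_tf:
        signatures["cholangiocyte_signature"] = GeneSet(
            "cholangiocyte_signature", regulons[chol_tf], source="planted progenitor program"
        )
    if up_tfs:
        stem_genes = set().union(*(regulons[tf] for tf in sorted(up_tfs)))
        signatures["stemness"] = GeneSet("stemness", stem_genes, source="planted progenitor programs")

    truth = GroundTruth(
        regulons=regulons,
        activity_profile=prof.copy(),
        differential_tfs_up=up_tfs,
        differential_tfs_down=down_tfs,
        hepatocyte_program_tf=hep_tf,
        cholangiocyte_program_tf=chol_tf,
    )

    panel = make_reference_panel(expr, n_ref_stages=9, gradient=1.0)

    return SimulatedDataset(
        expression=expr,
        peaks=peaks,
        motifs=motifs,
        signatures=signatures,
        panel=panel,
        truth=truth,
        tss_table=tss_table,
        config=config,
    )


def make_reference_panel(
    expr: ExpressionMatrix,
    n_ref_stages: int = 9,
    gradient: float = 1.0,
    stem_stage: str | None = None,
    mature_stage: str | None = None,
) -> ReferencePanel:
    """Reference developmental profiles interpolating stem-like -> mature-like.

    Column j of the panel is the (log-space) interpolation
    ``stem + gradient * j/(n-1) * (mature - stem)`` between the mean profile
    of the progenitor stage and the mean profile of the most mature stage,
    so correlation-based stage mapping has a known optimum: progenitor-stage
    samples match the earliest column, mature samples the latest. With
    ``gradient == 0`` every column is identical and mapping is degenerate
    (a warning is logged).
    """
    if n_ref_stages < 2:
        raise ConfigurationError("n_ref_stages: must be >= 2")
    if stem_stage is None:
        stem_stage = expr.stage_order[len(expr.stage_order) // 2]
    if mature_stage is None:
        mature_stage = expr.stage_order[-1]
    if gradient == 0:
        logger.warning("make_reference_panel: gradient=0 yields identical columns; stage mapping will tie")
    logv = expr.log_values()
    stem = logv[expr.samples_of_stage(stem_stage)].mean(axis=1)
    mature = logv[expr.samples_of_stage(mature_stage)].mean(axis=1)
    labels = [f"ref{j + 1:02d}" for j in range(n_ref_stages)]
    cols = {}
    for j, lab in enumerate(labels):
        w = j / (n_ref_stages - 1)
        cols[lab] = np.maximum(2.0 ** (stem + gradient * w * (mature - stem)) - 1.0, 0.0)
    return ReferencePanel(profiles=pd.DataFrame(cols), stage_labels=labels)
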