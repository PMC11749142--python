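"""Motif scanning over accessible peaks and motif-supported regulon pruning.

This is the multi-omic integration step: candidate co-expression regulons
survive only when the TF's binding motif is over-represented (hypergeometric
upper tail) among the accessible peaks assigned to its candidate targets in
at least one stage, and individual targets survive only when one of their
assigned peaks actually carries a motif hit.

Scanning is a plain log2-odds PWM scan of both strands over fixed-width
peak windows; windows containing N are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import (
    CandidateRegulon,
    MotifPWM,
    PeakSet,
    Regulon,
    peak_id,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 10_000
DEFAULT_ENRICHMENT_ALPHA = 0.05
DEFAULT_THRESHOLD_FRACTION = 0.8

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_CODE_LUT = np.full(256, -2, dtype=np.int64)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c


def default_score_threshold(pwm: MotifPWM, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Common PWM practice: a fraction of the maximum attainable log-odds."""
    return fraction * pwm.max_score


def _encode(seq: str) -> np.ndarray:
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == -2).any():
        bad = seq[int(np.argmax(codes == -2))]
        raise ValueError(f"invalid DNA character {bad!r}")
    return codes


def _scores_one_strand(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; NaN where the window contains N."""
    length = log_odds.shape[0]
    n_win = len(codes) - length + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    invalid = np.zeros(n_win, dtype=bool)
    for p in range(length):
        col = codes[p : p + n_win]
        bad = col < 0
        invalid |= bad
        scores += log_odds[p, np.where(bad, 0, col)]
    scores[invalid] = np.nan
    return scores


def scan_sequence(
    pwm: MotifPWM, seq: str, score_threshold: float | None = None
) -> list[tuple[int, str, float]]:
    """All motif hits in ``seq`` as (offset, strand, score).

    The score at an offset is the summed per-position log2(p/q) of the
    observed bases. Both strands are scanned; a minus-strand hit at offset i
    refers to the window seq[i:i+len] whose reverse complement matches the
    motif. Sequences shorter than the motif yield no hits.
    """
    if score_threshold is None:
        score_threshold = default_score_threshold(pwm)
    length = len(pwm)
    if len(seq) < length:
        return []
    lo = pwm.log_odds
    hits: list[tuple[int, str, float]] = []
    fwd = _scores_one_strand(lo, _encode(seq))
    rev = _scores_one_strand(lo, _encode(reverse_complement(seq)))
    n_win = len(fwd)
    with np.errstate(invalid="ignore"):
        fwd_hits = np.flatnonzero(fwd >= score_threshold)
        rev_hits = np.flatnonzero(rev >= score_threshold)
    for off in fwd_hits:
        hits.append((int(off), "+", float(fwd[off])))
    for j in rev_hits:
        # a hit at revcomp offset j covers seq[n_win-1-j : ...] on the minus strand
        hits.append((int(n_win - 1 - j), "-", float(rev[j])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def sequence_has_hit(pwm: MotifPWM, codes_fwd: np.ndarray, codes_rev: np.ndarray, score_threshold: float) -> bool:
    """Fast presence/absence check on pre-encoded forward/reverse codes."""
    lo = pwm.log_odds
    with np.errstate(invalid="ignore"):
        fwd = _scores_one_strand(lo, codes_fwd)
        if fwd.size and np.any(fwd >= score_threshold):
            return True
        rev = _scores_one_strand(lo, codes_rev)
        return bool(rev.size and np.any(rev >= score_threshold))


def assign_peaks_to_genes(
    peaks: PeakSet,
    tss_table: pd.DataFrame,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> dict[str, str]:
    """Assign each peak to the gene with the nearest TSS within ``max_distance``
    of the peak midpoint (ties go to the lexicographically smaller gene ID);
    unassigned peaks stay in the background universe."""
    if not {"chrom", "tss"}.issubset(tss_table.columns):
        raise ValueError("tss_table needs columns chrom, tss")
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for gene, row in tss_table.iterrows():
        by_chrom.setdefault(row["chrom"], []).append((float(row["tss"]), str(gene)))
    assignment: dict[str, str] = {}
    for _, row in peaks.unique_intervals().iterrows():
        pid = peak_id(row["chrom"], row["start"], row["end"])
        candidates = by_chrom.get(row["chrom"])
        if not candidates:
            continue
        mid = (row["start"] + row["end"]) / 2.0
        best = min(candidates, key=lambda c: (abs(mid - c[0]), c[1]))
        if abs(mid - best[0]) <= max_distance:
            assignment[pid] = best[1]
    return assignment


def motif_enrichment(
    hit_peaks: set[str], foreground: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p-value for over-representation of
    hit-bearing peaks in the foreground relative to the universe."""
    if not universe:
        raise ValueError("motif_enrichment: empty peak universe")
    if not foreground <= universe:
        raise ValueError("motif_enrichment: foreground must be a subset of the universe")
    M = len(universe)
    K = len(hit_peaks & universe)
    n = len(foreground)
    k = len(hit_peaks & foreground)
    return float(hypergeom.sf(k - 1, M, K, n))


@dataclass
class MotifSupport:
    """Per-TF motif evidence over the accessible peak landscape."""

    hit_peaks: dict[str, set[str]]  # tf -> peaks with >=1 motif hit
    hits_per_stage: dict[str, dict[str, int]]  # tf -> stage -> hit-bearing accessible peaks
    enrichment_p: dict[str, dict[str, float]]  # tf -> stage -> hypergeometric p
    supported_targets: dict[str, set[str]]  # tf -> targets with a hit-bearing assigned peak
    peak_to_gene: dict[str, str] = field(default_factory=dict)


def compute_motif_support(
    candidates: list[CandidateRegulon],
    motifs: dict[str, MotifPWM],
    peaks: PeakSet,
    tss_table: pd.DataFrame,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    score_threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> MotifSupport:
    """Scan every peak with every candidate TF's PWM and summarize, per TF
    and stage, the hit counts and the enrichment of hits among the peaks
    assigned to the TF's candidate targets (foreground) relative to all
    accessible peaks of that stage (universe)."""
    peak_to_gene = assign_peaks_to_genes(peaks, tss_table, max_distance)
    all_ids = peaks.peak_ids
    stage_peaks = {st: peaks.peaks_of_stage(st) for st in peaks.stages}
    encoded = {
        pid: (_encode(peaks.sequences[pid]), _encode(reverse_complement(peaks.sequences[pid])))
        for pid in all_ids
    }

    hit_peaks: dict[str, set[str]] = {}
    hits_per_stage: dict[str, dict[str, int]] = {}
    enrichment_p: dict[str, dict[str, float]] = {}
    supported: dict[str, set[str]] = {}

    for cand in candidates:
        tf = cand.tf
        if tf not in motifs:
            logger.warning("compute_motif_support: no motif for %s; regulon unsupported", tf)
            hit_peaks[tf] = set()
            hits_per_stage[tf] = {st: 0 for st in stage_peaks}
            enrichment_p[tf] = {st: 1.0 for st in stage_peaks}
            supported[tf] = set()
            continue
        pwm = motifs[tf]
        thr = default_score_threshold(pwm, score_threshold_fraction)
        hits = {pid for pid in all_ids if sequence_has_hit(pwm, *encoded[pid], thr)}
        hit_peaks[tf] = hits
        tf_fg_all = {pid for pid, g in peak_to_gene.items() if g in cand.targets}
        hits_per_stage[tf] = {}
        enrichment_p[tf] = {}
        for st, universe in stage_peaks.items():
            fg = tf_fg_all & universe
            hits_per_stage[tf][st] = len(hits & universe)
            enrichment_p[tf][st] = motif_enrichment(hits, fg, universe) if universe else 1.0
        supported[tf] = {peak_to_gene[pid] for pid in (tf_fg_all & hits)}
    return MotifSupport(
        hit_peaks=hit_peaks,
        hits_per_stage=hits_per_stage,
        enrichment_p=enrichment_p,
        supported_targets=supported,
        peak_to_gene=peak_to_gene,
    )


def prune_regulons(
    candidates: list[CandidateRegulon],
    support: MotifSupport,
    enrichment_alpha: float = DEFAULT_ENRICHMENT_ALPHA,
    min_size: int = 5,
) -> list[Regulon]:
    """Keep a regulon only if its motif is enriched (p <= alpha) in at least
    one stage's accessible peaks; within survivors drop targets lacking a
    motif-bearing assigned peak; drop regulons falling below ``min_size``."""
    pruned: list[Regulon] = []
    for cand in candidates:
        pvals = support.enrichment_p.get(cand.tf, {})
        if not pvals or min(pvals.values()) > enrichment_alpha:
            logger.info("prune_regulons: %s motif not enriched in any stage; dropped", cand.tf)
            continue
        kept = {
            g: s for g, s in cand.link_scores.items()
            if g in support.supported_targets.get(cand.tf, set())
        }
        if len(kept) < min_size:
            logger.info("prune_regulons: %s below min_size after motif pruning; dropped", cand.tf)
            continue
        pruned.append(Regulon(tf=cand.tf, link_scores=kept, supported=True))
    return pruned
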