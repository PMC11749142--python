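"""Candidate regulon construction from co-expression.

The network step is deliberately simple and fully deterministic: a TF's
candidate targets are the genes whose Spearman rank correlation with the TF
across all samples clears a threshold, keeping positive links only
(activating modules). Motif evidence from accessible chromatin then prunes
these candidates (see :mod:`hepatoregulon.motifs`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CandidateRegulon, ExpressionMatrix

logger = logging.getLogger(__name__)

# recall-oriented: with ~10 bulk samples the null Spearman sd is ~1/sqrt(n-1)
# ≈ 0.35, so no threshold separates signal from noise sharply; specificity
# is delegated to the motif-support pruning step
DEFAULT_CORR_THRESHOLD = 0.3
DEFAULT_MIN_SIZE = 5


def filter_regulators(
    expr: ExpressionMatrix,
    tf_list: set[str] | list[str],
    min_level: float = 1.0,
    min_stage_fraction: float = 1 / 3,
) -> set[str]:
    """Keep TFs whose stage-mean expression exceeds ``min_level`` in at least
    ``min_stage_fraction`` of the stages.

    TFs absent from the expression universe are dropped with a warning.
    An empty result is valid (downstream stages receive an empty set).
    """
    tf_list = set(tf_list)
    absent = tf_list - set(expr.genes)
    if absent:
        logger.warning("filter_regulators: %d TFs absent from expression: %s",
                       len(absent), sorted(absent))
    present = sorted(tf_list - absent)
    if not present:
        logger.warning("filter_regulators: no candidate TFs present in the expression matrix")
        return set()
    means = expr.stage_means().loc[present]
    frac_above = (means > min_level).mean(axis=1)
    kept = set(means.index[frac_above >= min_stage_fraction])
    if not kept:
        logger.warning("filter_regulators: no TF passed min_level=%s in >=%s of stages",
                       min_level, min_stage_fraction)
    return kept


def _rank_rows(values: pd.DataFrame) -> np.ndarray:
    """Average-tie ranks of each gene across samples (Spearman substrate)."""
    return values.rank(axis=1, method="average").to_numpy()


def spearman_to_tf(expr: ExpressionMatrix, tf: str) -> pd.Series:
    """Spearman rho of every gene against one TF across all samples.

    Computed as Pearson correlation of average-tie ranks; genes with
    constant expression get NaN.
    """
    ranks = _rank_rows(expr.values)
    genes = expr.genes
    t = ranks[genes.index(tf)]
    t_c = t - t.mean()
    t_ss = float(t_c @ t_c)
    if t_ss == 0:
        return pd.Series(np.nan, index=genes)
    g_c = ranks - ranks.mean(axis=1, keepdims=True)
    g_ss = (g_c**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (g_c @ t_c) / np.sqrt(g_ss * t_ss)
    rho[g_ss == 0] = np.nan
    return pd.Series(rho, index=genes)


def infer_candidate_regulons(
    expr: ExpressionMatrix,
    tfs: set[str] | list[str],
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[CandidateRegulon]:
    """Build one candidate regulon per TF from thresholded positive Spearman
    correlation across all samples.

    A TF with constant expression is skipped (correlation undefined);
    regulons smaller than ``min_size`` are dropped. The result is sorted by
    TF name, so it is invariant to gene and sample ordering of the input.
    """
    if len(expr.samples) < 3:
        raise ValueError("need >= 3 samples for rank correlation")
    if not 0 < corr_threshold <= 1:
        raise ValueError("corr_threshold must be in (0, 1]")
    out: list[CandidateRegulon] = []
    for tf in sorted(set(tfs)):
        rho = spearman_to_tf(expr, tf)
        if np.isnan(rho[tf]):
            logger.warning("infer_candidate_regulons: %s has constant expression; skipped", tf)
            continue
        links = rho.drop(index=tf)
        links = links[links >= corr_threshold].dropna()
        if len(links) < min_size:
            logger.info("infer_candidate_regulons: %s regulon below min_size (%d < %d); dropped",
                        tf, len(links), min_size)
            continue
        out.append(CandidateRegulon(tf=tf, link_scores=dict(links.sort_index())))
    return out
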