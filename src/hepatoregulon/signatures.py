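"""Single-sample signature scoring and developmental-stage mapping.

Implements the weighted running-sum single-sample enrichment statistic
(ssGSEA) for stemness/marker gene sets, a fast mean-z alternative for
marker signatures, Pearson correlation of regulon activity (or TF
expression) with signature scores, and the mapping of each sample onto a
reference developmental gradient by common-gene Pearson correlation of
log-scale profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, ReferencePanel

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.25


def ssgsea_score(expr_column: pd.Series, gene_set: GeneSet, tau: float = DEFAULT_TAU) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked by descending expression (ties broken by gene label so
    the score is deterministic); with rank score r_g = N - pos_g + 1, the
    statistic is ES = sum_i [P_in(i) - P_out(i)] where P_in is the
    r^tau-weighted in-set ECDF and P_out the unweighted out-of-set ECDF.
    Positive scores mean the set is concentrated among the sample's most
    highly expressed genes.
    """
    universe = list(expr_column.index)
    n = len(universe)
    in_set = expr_column.index.isin(gene_set.genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"gene set {gene_set.name!r} is disjoint from the expression universe")
    if n_in == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole universe; P_out undefined")
    values = expr_column.to_numpy(dtype=float)
    # descending by value, ties by gene label (stable, transform-invariant)
    order = np.lexsort((np.array(universe), -values))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(1, n + 1)
    r = (n - pos + 1).astype(float)
    w = np.where(in_set, r**tau, 0.0)
    in_sorted = in_set[order]
    w_sorted = w[order]
    p_in = np.cumsum(w_sorted) / w_sorted.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


@dataclass
class SignatureScores:
    """Set x sample matrix of enrichment scores plus per-set errors."""

    values: pd.DataFrame
    method: str
    errors: dict[str, str] = field(default_factory=dict)


def score_signatures(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    method: str = "ssgsea",
    normalize: bool = False,
    tau: float = DEFAULT_TAU,
) -> SignatureScores:
    """Score each gene set in each sample.

    ``method="ssgsea"`` uses the running-sum statistic; ``method="mean_z"``
    scores a set as the mean of its genes' per-gene z-scores (fast and
    sign-interpretable for marker signatures). With ``normalize`` (ssGSEA
    only) all scores are divided by the global max - min range across the
    score matrix, the usual convention for cross-sample comparability.
    Per-set failures are collected in ``errors`` and the run continues.
    """
    if method not in {"ssgsea", "mean_z"}:
        raise ValueError(f"unknown method {method!r}")
    rows: dict[str, pd.Series] = {}
    errors: dict[str, str] = {}
    if method == "mean_z":
        arr = expr.values.to_numpy(dtype=float)
        sd = arr.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (arr - arr.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd), 0.0)
        zdf = pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)
    for gs in sets:
        try:
            if method == "ssgsea":
                rows[gs.name] = pd.Series(
                    {s: ssgsea_score(expr.values[s], gs, tau) for s in expr.samples}
                )
            else:
                present = sorted(gs.genes & set(expr.genes))
                if not present:
                    raise ValueError(f"gene set {gs.name!r} is disjoint from the expression universe")
                rows[gs.name] = zdf.loc[present].mean(axis=0)
        except ValueError as exc:
            errors[gs.name] = str(exc)
            logger.warning("score_signatures: %s", exc)
    values = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=expr.samples)
    if normalize:
        if method != "ssgsea":
            raise ValueError("normalize applies to ssgsea scores only")
        if values.shape[1] < 2:
            raise ValueError("normalization undefined for a single-sample matrix")
        rng_ = float(values.to_numpy().max() - values.to_numpy().min())
        if rng_ == 0:
            raise ValueError("normalization undefined: zero score range")
        values = values / rng_
    return SignatureScores(values=values, method=method, errors=errors)


def signature_correlation(act_row: pd.Series, sig_row: pd.Series) -> tuple[float, float]:
    """Pearson r (with two-sided t-transform p, df n-2) between a regulon's
    activity (or its TF's expression) and a signature score across samples.

    Zero variance in either vector makes r undefined; (nan, nan) is
    returned and a warning logged.
    """
    common = act_row.index.intersection(sig_row.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    x = act_row[common].to_numpy(dtype=float)
    y = sig_row[common].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        logger.warning("signature_correlation: zero variance; r undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def common_expressed_genes(expr: ExpressionMatrix, panel: ReferencePanel) -> list[str]:
    """Genes expressed (nonzero in >= 1 column) in both datasets."""
    expr_on = expr.values.index[(expr.values > 0).any(axis=1)]
    panel_on = panel.profiles.index[(panel.profiles > 0).any(axis=1)]
    return sorted(set(expr_on) & set(panel_on))


def stage_similarity(expr: ExpressionMatrix, panel: ReferencePanel) -> pd.DataFrame:
    """Sample x reference-stage Pearson correlation over the common expressed
    genes, computed on log2(x+1) profiles.

    The argmax along each row maps a sample onto the reference
    developmental gradient (progenitor-like samples match early columns,
    mature samples late ones).
    """
    common = common_expressed_genes(expr, panel)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common expressed genes; need >= 3")
    ex = expr.log_values().loc[common]
    pa = np.log2(panel.profiles.loc[common] + 1.0)
    out = pd.DataFrame(index=expr.samples, columns=panel.stage_labels, dtype=float)
    for s in expr.samples:
        xs = ex[s].to_numpy(dtype=float)
        for ref in panel.stage_labels:
            ys = pa[ref].to_numpy(dtype=float)
            if xs.std() == 0 or ys.std() == 0:
                out.loc[s, ref] = np.nan
            else:
                out.loc[s, ref] = stats.pearsonr(xs, ys)[0]
    return out
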