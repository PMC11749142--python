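"""Differential regulon activity and master-TF candidate ranking.

Per regulon and stage pair, an F test on the activity variances gates the
choice between the pooled-variance Student t test (variances compatible)
and the Welch t test (otherwise); p-values are Benjamini-Hochberg adjusted
across the regulons of a comparison, and effect size is the log2 ratio of
mean activities. Candidate master TFs are regulons significant in BOTH
stage transitions with opposite fold-change signs, ranked by a combined
FDR x fold-change score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datatypes import ActivityMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_VAR = 0.05
DEFAULT_ALPHA_FDR = 0.05
DEFAULT_FC_MIN = 0.0
DEFAULT_TOP_K = 4
_FC_EPSILON = 1e-6


def variance_gate(
    x: np.ndarray, y: np.ndarray, alpha_var: float = DEFAULT_ALPHA_VAR
) -> tuple[float, float, bool]:
    """Two-sided variance-ratio F test deciding the t-test branch.

    Returns (f_stat, f_p, equal_var) with f_stat = s_x^2 / s_y^2 and the
    two-sided p as 2 * min(lower tail, upper tail) capped at 1; the pooled
    Student branch is used when f_p > alpha_var.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("variance_gate needs >= 2 replicates per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        logger.info("variance_gate: both groups have zero variance")
        return 1.0, 1.0, True
    if vx == 0 or vy == 0:
        return (0.0 if vx == 0 else np.inf), 0.0, False
    f = vx / vy
    dist = stats.f(len(x) - 1, len(y) - 1)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return float(f), float(p), bool(p > alpha_var)


def two_sample_test(
    x: np.ndarray, y: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    """Student (pooled) or Welch two-sample t test, two-sided.

    Two constant and equal groups give (0, 1) rather than NaN so that
    zero-variance activity rows are reported as non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        return 0.0, 1.0
    return t, p


def log2_activity_fc(x: np.ndarray, y: np.ndarray) -> float:
    """log2(mean(y) / mean(x)) with an epsilon guard for zero means
    (activities are AUCs, hence nonnegative)."""
    mx = float(np.mean(x))
    my = float(np.mean(y))
    if mx == 0 and my == 0:
        logger.info("log2_activity_fc: both means zero; fold change set to 0")
        return 0.0
    if mx == 0 or my == 0:
        logger.info("log2_activity_fc: zero mean activity replaced by epsilon %g", _FC_EPSILON)
    mx = max(mx, _FC_EPSILON)
    my = max(my, _FC_EPSILON)
    return float(np.log2(my / mx))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_regulons(
    act: ActivityMatrix,
    stage_a: str,
    stage_b: str,
    tf_expression: pd.DataFrame | None = None,
    alpha_var: float = DEFAULT_ALPHA_VAR,
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Volcano table of regulon activity between two stages.

    Columns: mean_a, mean_b, log2_fc, f_stat, f_p, test_branch, t_stat, p,
    fdr, neg_log10_fdr, dot_size (mean TF log expression over both stages,
    NaN without ``tf_expression``), dot_size_centered, direction
    (up_in_b / down_in_b / ns at ``alpha_fdr`` and ``fc_min``).
    """
    for st in (stage_a, stage_b):
        if st not in set(act.stage_of[list(act.samples)]):
            raise ValueError(f"stage {st!r} absent from the activity matrix")
    cols_a = act.samples_of_stage(stage_a)
    cols_b = act.samples_of_stage(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both stages need >= 2 replicates")
    records = []
    for reg in act.regulons:
        x = act.values.loc[reg, cols_a].to_numpy(dtype=float)
        y = act.values.loc[reg, cols_b].to_numpy(dtype=float)
        f_stat, f_p, equal = variance_gate(x, y, alpha_var)
        t_stat, p = two_sample_test(x, y, equal)
        records.append(
            {
                "regulon": reg,
                "mean_a": float(x.mean()),
                "mean_b": float(y.mean()),
                "log2_fc": log2_activity_fc(x, y),
                "f_stat": f_stat,
                "f_p": f_p,
                "test_branch": "student" if equal else "welch",
                "t_stat": t_stat,
                "p": p,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("regulon")
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    with np.errstate(divide="ignore"):
        table["neg_log10_fdr"] = -np.log10(table["fdr"].clip(lower=np.finfo(float).tiny))
    if tf_expression is not None:
        both = cols_a + cols_b
        dot = tf_expression.reindex(table.index)[both].mean(axis=1)
        table["dot_size"] = dot
        table["dot_size_centered"] = dot - dot.mean()
    else:
        table["dot_size"] = np.nan
        table["dot_size_centered"] = np.nan
    sig = (table["fdr"] <= alpha_fdr) & (table["log2_fc"].abs() >= fc_min) & (table["log2_fc"] != 0)
    table["direction"] = np.where(
        sig & (table["log2_fc"] > 0), "up_in_b", np.where(sig & (table["log2_fc"] < 0), "down_in_b", "ns")
    )
    return table


@dataclass
class CandidateRanking:
    """Ranked master-TF candidates for one direction of the fate switch."""

    direction: str  # "progenitor-enriched" or "mature-enriched"
    table: pd.DataFrame  # index regulon; combined_score, per-transition stats, top_k flag

    @property
    def top(self) -> list[str]:
        return list(self.table.index[self.table["top_k"]])


def _combined_score(row: pd.Series) -> float:
    tiny = np.finfo(float).tiny
    return float(
        -np.log10(max(row["fdr_1"], tiny)) * abs(row["log2_fc_1"])
        + -np.log10(max(row["fdr_2"], tiny)) * abs(row["log2_fc_2"])
    )


def overlap_and_rank(
    diff_1: pd.DataFrame,
    diff_2: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    scorer: str = "weighted_fdr_fc",
) -> tuple[CandidateRanking, CandidateRanking]:
    """Overlap the significant regulons of the two stage transitions and rank
    the opposite-sign survivors.

    Progenitor-enriched candidates rise in transition 1 (mature -> progenitor)
    and fall in transition 2 (progenitor -> re-differentiated); mature-enriched
    candidates do the reverse. The default score integrates FDR and fold
    change per transition as sum(-log10 fdr * |log2 fc|); ``scorer=
    "rank_product"`` instead multiplies the per-transition ranks of that
    quantity (smaller product = stronger candidate).
    """
    if scorer not in {"weighted_fdr_fc", "rank_product"}:
        raise ValueError(f"unknown scorer {scorer!r}")
    shared = diff_1.index.intersection(diff_2.index)
    merged = pd.DataFrame(
        {
            "log2_fc_1": diff_1.loc[shared, "log2_fc"],
            "fdr_1": diff_1.loc[shared, "fdr"],
            "direction_1": diff_1.loc[shared, "direction"],
            "log2_fc_2": diff_2.loc[shared, "log2_fc"],
            "fdr_2": diff_2.loc[shared, "fdr"],
            "direction_2": diff_2.loc[shared, "direction"],
        }
    )

    def build(direction: str, d1: str, d2: str) -> CandidateRanking:
        sel = merged[(merged["direction_1"] == d1) & (merged["direction_2"] == d2)].copy()
        if len(sel):
            sel["combined_score"] = sel.apply(_combined_score, axis=1)
            if scorer == "rank_product":
                tiny = np.finfo(float).tiny
                s1 = (-np.log10(sel["fdr_1"].clip(lower=tiny))) * sel["log2_fc_1"].abs()
                s2 = (-np.log10(sel["fdr_2"].clip(lower=tiny))) * sel["log2_fc_2"].abs()
                sel["rank_product"] = s1.rank(ascending=False) * s2.rank(ascending=False)
                sel = sel.sort_values(["rank_product", "combined_score"], ascending=[True, False])
            else:
                sel = sel.sort_values("combined_score", ascending=False)
            sel["top_k"] = [i < top_k for i in range(len(sel))]
        else:
            sel["combined_score"] = pd.Series(dtype=float)
            sel["top_k"] = pd.Series(dtype=bool)
        return CandidateRanking(direction=direction, table=sel)

    progenitor = build("progenitor-enriched", "up_in_b", "down_in_b")
    mature = build("mature-enriched", "down_in_b", "up_in_b")
    return progenitor, mature


def group_regulons(
    act: ActivityMatrix,
    k: int = 4,
    seed: int = 0,
    progenitor_stage: str | None = None,
) -> pd.Series:
    """K-means grouping of regulons by z-scored stage-mean activity profile.

    Groups are relabeled deterministically by their centroid's value at the
    progenitor stage (default: middle of ``stage_order``), ascending: G1 has
    the most mature-skewed profile, Gk the most progenitor-skewed one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    means = act.stage_means()
    if len(means) < k:
        raise ValueError(f"only {len(means)} regulons for k={k}; use a smaller k")
    arr = means.to_numpy(dtype=float)
    sd = arr.std(axis=1, keepdims=True)
    mu = arr.mean(axis=1, keepdims=True)
    z = np.where(sd > 0, (arr - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    if len(np.unique(z.round(12), axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct activity profiles; use a smaller k")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(z)
    if progenitor_stage is None:
        progenitor_stage = act.stage_order[len(act.stage_order) // 2]
    stage_idx = act.stage_order.index(progenitor_stage)
    order = np.argsort(km.cluster_centers_[:, stage_idx], kind="stable")
    relabel = {int(cl): f"G{pos + 1}" for pos, cl in enumerate(order)}
    return pd.Series([relabel[int(lab)] for lab in labels], index=means.index, name="group")
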