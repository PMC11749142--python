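"""End-to-end orchestration: filtered regulators -> co-expression candidate
regulons -> motif-supported regulons -> rank-AUC activity -> differential
activity over the two stage transitions -> overlap ranking of master-TF
candidates, plus signature scoring and developmental-stage mapping.

:func:`analyze` chains the stages on in-memory objects;
:func:`run_pipeline` is the file-driven wrapper used by the CLI, writing
every output table plus a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import SMALL_UNIVERSE_TOP_FRACTION, regulon_expression, score_activity
from .datatypes import ExpressionMatrix, GeneSet, MotifPWM, PeakSet, ReferencePanel, Regulon
from .differential import (
    CandidateRanking,
    differential_regulons,
    group_regulons,
    overlap_and_rank,
)
from .motifs import MotifSupport, compute_motif_support, prune_regulons
from .regulons import filter_regulators, infer_candidate_regulons
from .signatures import SignatureScores, score_signatures, signature_correlation, stage_similarity

logger = logging.getLogger(__name__)


@dataclass
class Params:
    """All tunable analysis parameters (defaults match the documented study
    conditions: small simulated universes, 3 stages x 3 replicates)."""

    min_level: float = 1.0
    min_stage_fraction: float = 1 / 3
    corr_threshold: float = 0.3
    min_size: int = 5
    enrichment_alpha: float = 0.05
    max_distance: float = 10_000
    score_threshold_fraction: float = 0.8
    top_fraction: float = SMALL_UNIVERSE_TOP_FRACTION
    alpha_var: float = 0.05
    alpha_fdr: float = 0.05
    fc_min: float = 0.0
    top_k: int = 4
    tau: float = 0.25
    k_groups: int = 4
    seed: int = 0


@dataclass
class AnalysisResult:
    kept_tfs: set[str]
    candidates: list[Regulon]
    support: MotifSupport
    regulons: list[Regulon]
    activity: "object"
    tf_expression: pd.DataFrame
    transitions: list[tuple[str, str]]
    diff_tables: dict[str, pd.DataFrame]
    progenitor_ranking: CandidateRanking
    mature_ranking: CandidateRanking
    groups: pd.Series | None
    signature_scores: SignatureScores | None
    marker_scores: SignatureScores | None
    correlations: pd.DataFrame | None
    similarity: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)


def analyze(
    expr: ExpressionMatrix,
    tf_list: set[str] | list[str],
    peaks: PeakSet,
    motifs: dict[str, MotifPWM],
    tss_table: pd.DataFrame,
    gene_sets: list[GeneSet] | None = None,
    panel: ReferencePanel | None = None,
    params: Params | None = None,
) -> AnalysisResult:
    """Run the full inference chain on in-memory inputs."""
    params = params or Params()
    warnings: list[str] = []

    kept = filter_regulators(expr, tf_list, params.min_level, params.min_stage_fraction)
    if not kept:
        raise ValueError("no regulator passed the expression filter; cannot build regulons")
    candidates = infer_candidate_regulons(expr, kept, params.corr_threshold, params.min_size)
    if not candidates:
        raise ValueError("no candidate regulon reached min_size; lower corr_threshold or min_size")
    support = compute_motif_support(
        candidates, motifs, peaks, tss_table,
        max_distance=params.max_distance,
        score_threshold_fraction=params.score_threshold_fraction,
    )
    regulons = prune_regulons(candidates, support, params.enrichment_alpha, params.min_size)
    if not regulons:
        raise ValueError("no regulon survived motif pruning")

    activity = score_activity(expr, regulons, params.top_fraction, seed=params.seed)
    tf_expr = regulon_expression(expr, regulons)

    transitions = list(zip(expr.stage_order[:-1], expr.stage_order[1:]))
    diff_tables: dict[str, pd.DataFrame] = {}
    for a, b in transitions:
        diff_tables[f"{a}->{b}"] = differential_regulons(
            activity, a, b, tf_expression=tf_expr,
            alpha_var=params.alpha_var, alpha_fdr=params.alpha_fdr, fc_min=params.fc_min,
        )
    if len(transitions) < 2:
        raise ValueError("master-TF ranking needs at least 3 stages (2 transitions)")
    t1, t2 = transitions[0], transitions[1]
    progenitor, mature = overlap_and_rank(
        diff_tables[f"{t1[0]}->{t1[1]}"], diff_tables[f"{t2[0]}->{t2[1]}"], top_k=params.top_k
    )

    groups: pd.Series | None = None
    try:
        groups = group_regulons(activity, k=params.k_groups, seed=params.seed)
    except ValueError as exc:
        warnings.append(f"regulon grouping skipped: {exc}")
        logger.warning("analyze: %s", warnings[-1])

    sig_scores = marker_scores = None
    correlations = None
    if gene_sets:
        sig_scores = score_signatures(expr, gene_sets, method="ssgsea", tau=params.tau)
        marker_scores = score_signatures(expr, gene_sets, method="mean_z")
        rows = []
        for reg in regulons:
            for gs in gene_sets:
                if gs.name not in marker_scores.values.index:
                    continue
                sig_row = marker_scores.values.loc[gs.name]
                r_act, p_act = signature_correlation(activity.values.loc[reg.tf], sig_row)
                r_expr, p_expr = signature_correlation(tf_expr.loc[reg.tf], sig_row)
                rows.append(
                    {
                        "regulon": reg.tf,
                        "signature": gs.name,
                        "r_activity": r_act,
                        "p_activity": p_act,
                        "r_expression": r_expr,
                        "p_expression": p_expr,
                    }
                )
        correlations = pd.DataFrame(rows)

    similarity = stage_similarity(expr, panel) if panel is not None else None

    return AnalysisResult(
        kept_tfs=kept,
        candidates=candidates,
        support=support,
        regulons=regulons,
        activity=activity,
        tf_expression=tf_expr,
        transitions=transitions,
        diff_tables=diff_tables,
        progenitor_ranking=progenitor,
        mature_ranking=mature,
        groups=groups,
        signature_scores=sig_scores,
        marker_scores=marker_scores,
        correlations=correlations,
        similarity=similarity,
        warnings=warnings,
    )


@dataclass
class RunConfig:
    """File-driven run configuration (YAML-serializable)."""

    counts: str
    metadata: str
    peaks: dict[str, str]  # stage -> BED path
    fasta: str
    motifs: str
    tss: str
    outdir: str
    signatures: str | None = None
    panel: str | None = None
    tf_list: list[str] | None = None  # default: motif names
    peak_width: int = 500
    normalize_expression: bool = False
    params: Params = field(default_factory=Params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = Params(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _comment_header(params: Params) -> str:
    return f"# hepatoregulon {__version__} " + " ".join(
        f"{k}={v}" for k, v in asdict(params).items()
    )


def _write_table(df: pd.DataFrame, path: Path, params: Params, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params) + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from files and write every output table plus
    a run manifest; returns the manifest dict."""
    from .io import read_bed_fasta, read_expression, read_gmt, read_meme, read_panel, read_tss_table

    params = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = read_expression(config.counts, config.metadata, normalize=config.normalize_expression)
    peaks = read_bed_fasta(config.peaks, config.fasta, width=config.peak_width)
    motifs = read_meme(config.motifs)
    tss = read_tss_table(config.tss)
    gene_sets = read_gmt(config.signatures) if config.signatures else None
    panel = read_panel(config.panel) if config.panel else None
    tf_list = config.tf_list or sorted(motifs)

    result = analyze(expr, tf_list, peaks, motifs, tss, gene_sets, panel, params)

    # regulon table + summary
    reg_rows = [
        {"tf": reg.tf, "target": t, "link_score": s}
        for reg in result.regulons
        for t, s in sorted(reg.link_scores.items())
    ]
    _write_table(pd.DataFrame(reg_rows).set_index("tf"), outdir / "regulons.tsv", params, "tf")
    (outdir / "regulons.json").write_text(
        json.dumps(
            {reg.tf: {"size": reg.size, "targets": sorted(reg.targets)} for reg in result.regulons},
            indent=2,
        )
        + "\n"
    )

    # motif hit/enrichment tables
    enr_rows = [
        {"tf": tf, "stage": st, "hits": result.support.hits_per_stage[tf][st], "p": p}
        for tf, per_stage in result.support.enrichment_p.items()
        for st, p in per_stage.items()
    ]
    _write_table(pd.DataFrame(enr_rows).set_index("tf"), outdir / "motif_enrichment.tsv", params, "tf")

    _write_table(result.activity.values, outdir / "activity.tsv", params, "regulon")
    _write_table(result.tf_expression, outdir / "regulon_expression.tsv", params, "regulon")

    for name, table in result.diff_tables.items():
        safe = name.replace("->", "_to_")
        _write_table(table, outdir / f"differential_{safe}.tsv", params, "regulon")
        volcano = table[["log2_fc", "neg_log10_fdr", "dot_size", "direction"]]
        _write_table(volcano, outdir / f"volcano_{safe}.tsv", params, "regulon")

    rankings = {
        r.direction: {
            "order": list(r.table.index),
            "top_k": r.top,
            "combined_score": {k: float(v) for k, v in r.table["combined_score"].items()},
        }
        for r in (result.progenitor_ranking, result.mature_ranking)
    }
    (outdir / "rankings.json").write_text(json.dumps(rankings, indent=2) + "\n")

    if result.groups is not None:
        _write_table(result.groups.to_frame(), outdir / "regulon_groups.tsv", params, "regulon")
    if result.signature_scores is not None:
        _write_table(result.signature_scores.values, outdir / "signature_scores_ssgsea.tsv", params, "signature")
        _write_table(result.marker_scores.values, outdir / "signature_scores_mean_z.tsv", params, "signature")
        _write_table(result.correlations.set_index("regulon"), outdir / "signature_correlations.tsv", params, "regulon")
    if result.similarity is not None:
        _write_table(result.similarity, outdir / "stage_similarity.tsv", params, "sample")

    manifest = {
        "software": {"name": "hepatoregulon", "version": __version__},
        "config": {**{k: v for k, v in asdict(config).items() if k != "params"}, "params": asdict(params)},
        "seeds": {"analysis_seed": params.seed, "tie_seeds": result.activity.tie_seeds},
        "counts": {
            "genes": len(expr.genes),
            "samples": len(expr.samples),
            "tfs_filtered": len(result.kept_tfs),
            "candidate_regulons": len(result.candidates),
            "motif_supported_regulons": len(result.regulons),
            "significant_per_transition": {
                name: int((tbl["direction"] != "ns").sum()) for name, tbl in result.diff_tables.items()
            },
        },
        "warnings": result.warnings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
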