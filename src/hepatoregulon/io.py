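"""Readers and writers for the plain-text interchange formats.

Expression and metadata travel as TSV, gene sets as GMT, motifs as MEME
minimal format, peaks as per-stage BED (0-based half-open) plus a FASTA of
peak sequences keyed ``chrom:start-end``, and the planted ground truth /
rankings / run manifest as JSON. Every writer/reader pair round-trips
exactly for valid inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    ExpressionMatrix,
    GeneSet,
    GroundTruth,
    MotifPWM,
    PeakSet,
    ReferencePanel,
    peak_id,
)
from .simulate import SimulatedDataset


# ---------------------------------------------------------------- expression

def write_expression(expr: ExpressionMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample": expr.samples,
            "stage": [expr.stage_of[s] for s in expr.samples],
            "replicate": [s.rsplit("_r", 1)[-1] if "_r" in s else "1" for s in expr.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression(
    counts_path: str | Path,
    metadata_path: str | Path,
    normalize: bool = False,
    stage_order: list[str] | None = None,
) -> ExpressionMatrix:
    """Load a gene x sample TSV plus sample metadata (sample, stage[, replicate]).

    With ``normalize`` the counts are log1p-CPM transformed. Samples present
    in the matrix but missing from the metadata are an error.
    """
    df = pd.read_csv(counts_path, sep="\t", float_precision="round_trip", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample", "stage"}.issubset(meta.columns):
        raise ValueError("metadata needs columns: sample, stage")
    stage_of = pd.Series(meta["stage"].values, index=meta["sample"].values)
    missing = [s for s in df.columns if s not in stage_of.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    if stage_order is None:
        stage_order = list(dict.fromkeys(meta["stage"]))
    log_transformed = False
    if normalize:
        totals = df.sum(axis=0)
        df = np.log1p(df / totals * 1e6)
        log_transformed = True
    return ExpressionMatrix(
        values=df, stage_of=stage_of, stage_order=stage_order, log_transformed=log_transformed
    )


# ----------------------------------------------------------------- gene sets

def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.source}\t{genes}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValueError(f"GMT line {line_no}: set {parts[0]!r} has no genes")
        out.append(GeneSet(name=parts[0], genes={p for p in parts[2:] if p.strip()}, source=parts[1]))
    return out


# -------------------------------------------------------------------- motifs

def write_meme(pwms: dict[str, MotifPWM], path: str | Path) -> None:
    """MEME minimal format; probabilities are written at full precision so the
    write/read pair round-trips exactly."""
    first = next(iter(pwms.values()))
    bg = first.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.17g} C {bg[1]:.17g} G {bg[2]:.17g} T {bg[3]:.17g}\n\n")
        for name, pwm in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, pseudocount: float = 0.0) -> dict[str, MotifPWM]:
    """Parse MEME minimal motifs into PWMs.

    Matrices are taken as written (rows validated to sum to 1 within 1e-6,
    then renormalized exactly); pass a nonzero ``pseudocount`` when loading
    raw motif collections that may contain zero probabilities. The parsing
    is done here rather than through a motif library so that probabilities
    survive a write/read cycle exactly instead of being quantized to
    per-site counts.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("MEME version"):
        raise ValueError("not a MEME minimal file: missing 'MEME version' header")
    background = np.full(4, 0.25)
    out: dict[str, MotifPWM] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts) - 1, 2)}
            background = np.array([freq[b] for b in "ACGT"], dtype=float)
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {name}: missing letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing letter-probability matrix")
            header = lines[i].strip()
            fields = dict(
                zip(header.replace("letter-probability matrix:", "").split()[::2],
                    header.replace("letter-probability matrix:", "").split()[1::2])
            )
            width = int(fields["w="]) if "w=" in fields else None
            i += 1
            rows = []
            while i < len(lines) and lines[i].strip() and not lines[i].strip().startswith("MOTIF"):
                vals = lines[i].split()
                if len(vals) != 4:
                    raise ValueError(f"motif {name}: matrix row must have 4 values, got {len(vals)}")
                rows.append([float(v) for v in vals])
                i += 1
            mat = np.array(rows, dtype=float)
            if width is not None and len(mat) != width:
                raise ValueError(f"motif {name}: declared width {width} != {len(mat)} rows")
            bad = ~np.isclose(mat.sum(axis=1), 1.0, rtol=1e-9, atol=1e-6)
            if bad.any():
                raise ValueError(
                    f"motif {name}: probability rows do not sum to 1 "
                    f"(position {int(np.flatnonzero(bad)[0])})"
                )
            out[name] = MotifPWM(tf=name, matrix=mat, background=background, pseudocount=pseudocount)
            continue
        i += 1
    if not out:
        raise ValueError("no MOTIF entries found")
    return out


# --------------------------------------------------------------- peaks (BED)

def write_peaks(peaks: PeakSet, outdir: str | Path) -> dict[str, Path]:
    """Per-stage BED files plus one FASTA of unique peak sequences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for stage in peaks.stages:
        sub = peaks.intervals[peaks.intervals["stage"] == stage]
        bed = sub[["chrom", "start", "end"]].copy()
        bed["name"] = [peak_id(r["chrom"], r["start"], r["end"]) for _, r in sub.iterrows()]
        p = outdir / f"peaks_{stage}.bed"
        bed.to_csv(p, sep="\t", header=False, index=False)
        paths[stage] = p
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in peaks.sequences.items()
    ]
    fasta = outdir / "peaks.fasta"
    SeqIO.write(records, fasta, "fasta")
    paths["fasta"] = fasta
    return paths


def read_bed_fasta(
    bed_paths: dict[str, str | Path], fasta_path: str | Path, width: int = 500
) -> PeakSet:
    """Load per-stage BED intervals and their sequences; width and sequence
    presence are cross-checked."""
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows = []
    for stage, path in bed_paths.items():
        bed = pd.read_csv(path, sep="\t", header=None)
        for _, r in bed.iterrows():
            chrom, start, end = str(r[0]), int(r[1]), int(r[2])
            if end - start != width:
                raise ValueError(f"BED interval {chrom}:{start}-{end} has width {end - start}, expected {width}")
            pid = peak_id(chrom, start, end)
            if pid not in sequences:
                raise ValueError(f"peak {pid} missing from FASTA")
            if len(sequences[pid]) != width:
                raise ValueError(f"FASTA record {pid} length {len(sequences[pid])} != width {width}")
            rows.append({"chrom": chrom, "start": start, "end": end, "stage": stage})
    return PeakSet(intervals=pd.DataFrame(rows), sequences=sequences, width=width)


# ------------------------------------------------------------- panel / truth

def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    df = panel.profiles.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_panel(path: str | Path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", index_col=0)
    return ReferencePanel(profiles=df, stage_labels=list(df.columns))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "regulons": {tf: sorted(tg) for tf, tg in truth.regulons.items()},
        "activity_profile": {
            "index": list(truth.activity_profile.index),
            "columns": list(truth.activity_profile.columns),
            "values": truth.activity_profile.to_numpy().tolist(),
        },
        "differential_tfs_up": sorted(truth.differential_tfs_up),
        "differential_tfs_down": sorted(truth.differential_tfs_down),
        "hepatocyte_program_tf": truth.hepatocyte_program_tf,
        "cholangiocyte_program_tf": truth.cholangiocyte_program_tf,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    prof = pd.DataFrame(
        payload["activity_profile"]["values"],
        index=payload["activity_profile"]["index"],
        columns=payload["activity_profile"]["columns"],
    )
    return GroundTruth(
        regulons={tf: set(tg) for tf, tg in payload["regulons"].items()},
        activity_profile=prof,
        differential_tfs_up=set(payload["differential_tfs_up"]),
        differential_tfs_down=set(payload["differential_tfs_down"]),
        hepatocyte_program_tf=payload.get("hepatocyte_program_tf", ""),
        cholangiocyte_program_tf=payload.get("cholangiocyte_program_tf", ""),
    )


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    df = tss.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ------------------------------------------------------------ whole datasets

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, object]:
    """Write every artifact of a simulated dataset; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, outdir / "counts.tsv", outdir / "metadata.tsv")
    peak_paths = write_peaks(dataset.peaks, outdir)
    write_meme(dataset.motifs, outdir / "motifs.meme")
    write_gmt(list(dataset.signatures.values()), outdir / "signatures.gmt")
    write_panel(dataset.panel, outdir / "reference_panel.tsv")
    write_ground_truth(dataset.truth, outdir / "ground_truth.json")
    write_tss_table(dataset.tss_table, outdir / "tss.tsv")
    return {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "peaks": {st: p for st, p in peak_paths.items() if st != "fasta"},
        "fasta": peak_paths["fasta"],
        "motifs": outdir / "motifs.meme",
        "signatures": outdir / "signatures.gmt",
        "panel": outdir / "reference_panel.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "tss": outdir / "tss.tsv",
    }
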