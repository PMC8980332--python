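"""End-to-end prescreen orchestration.

The prescreen chains: marker selection on the clustered count matrix,
TF-panel intersection, peak nomination in the target gene's flanking
region, motif scanning of each candidate, TFBS-density computation and
quadrant classification.  Every output TSV starts with ``#`` header
lines echoing the exact thresholds used, and a run manifest records the
configuration hash and input-file hashes so reruns can be verified
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .density import ClassifierConfig, density_table, detect_tandem_repeats, tfbs_density
from .markers import (
    find_markers,
    markers_to_frame,
    qc_filter_cells,
    read_counts_tsv,
    read_tf_list,
    select_tfs,
)
from .motifs import load_jaspar_pfm, read_fasta, write_fasta
from .peaks import nominate_crms, read_bed12_genes, read_coverage, write_peaks_bed, Peak


@dataclass
class RunConfig:
    """All prescreen inputs and thresholds.

    Defaults equal the method's stated parameters: 0.80 relative motif
    threshold; raw-score cuts 10/11; density cuts 1.7/1.0 per 100 bp;
    5 bp hit merging; peak tip >= 20 with 20%-of-tip boundaries;
    marker filters log2FC > 2, p < 0.05, min_pct 0.25; cell QC
    mito < 20% and > 900 genes.
    """

    counts: str = ""
    clusters: str = ""
    tf_list: str = ""
    pfm: str = ""
    coverage: str = ""
    genes: str = ""
    genome: str = ""
    gene_id: str = ""
    target_cluster: str = ""
    outdir: str = "prescreen_out"
    seed: int = 0
    relative_threshold: float = 0.80
    thr_low: float = 10.0
    thr_high: float = 11.0
    density_x_cut: float = 1.7
    density_y_cut: float = 1.0
    merge_window_bp: int = 5
    combine_rule: str = "AND"
    tip_min: float = 20.0
    boundary_frac: float = 0.2
    log2fc_min: float = 2.0
    p_max: float = 0.05
    min_pct: float = 0.25
    max_mito_frac: float = 0.20
    min_genes: int = 900
    mask_repeats: bool = True


class PrescreenError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(cfg: RunConfig) -> dict:
    # outdir is where results land, not part of what was computed
    return {k: v for k, v in asdict(cfg).items() if k != "outdir"}


def _config_header(cfg: RunConfig) -> str:
    return "".join(f"# {k}={v}\n" for k, v in sorted(_config_echo(cfg).items()))


def _write_table(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_config_header(cfg))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_prescreen(cfg: RunConfig) -> dict:
    """Run the full prescreen; returns a summary dict and writes TSV/FASTA/BED
    outputs plus ``manifest.json`` under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. markers and TF panel
    try:
        mat = read_counts_tsv(cfg.counts, cfg.clusters)
        mat = qc_filter_cells(mat, cfg.max_mito_frac, cfg.min_genes)
        markers = find_markers(
            mat,
            cfg.target_cluster,
            log2fc_min=cfg.log2fc_min,
            p_max=cfg.p_max,
            min_pct=cfg.min_pct,
        )
    except FileNotFoundError as exc:
        raise PrescreenError(
            f"marker stage: missing input {exc.filename!r} "
            "(produce counts/clusters first, e.g. with `crmscan simulate`)"
        ) from exc
    except Exception as exc:
        raise PrescreenError(f"marker stage: {exc}") from exc
    try:
        tfs = read_tf_list(cfg.tf_list)
    except FileNotFoundError as exc:
        raise PrescreenError(
            f"TF-panel stage: missing TF list {cfg.tf_list!r} "
            "(a TF panel is produced by `crmscan markers`)"
        ) from exc
    panel = select_tfs(markers, tfs)
    panel_names = {r.gene_id for r in panel}
    if not panel:
        raise PrescreenError(
            "TF-panel stage: no passing marker is a TF; cannot scan candidates"
        )

    # 2. motif profiles restricted to the panel
    try:
        profiles = [p for p in load_jaspar_pfm(cfg.pfm) if p.tf_name in panel_names]
    except Exception as exc:
        raise PrescreenError(f"motif stage: {exc}") from exc
    if not profiles:
        raise PrescreenError("motif stage: no PFM matches a panel TF name")

    # 3. candidate nomination
    try:
        genes = read_bed12_genes(cfg.genes)
        gene = next(g for g in genes if g.gene_id == cfg.gene_id)
        tracks = read_coverage(cfg.coverage)
        track = next(t for t in tracks if t.chrom == gene.chrom)
        genome = {s.id: s.bases for s in read_fasta(cfg.genome)}
        candidates = nominate_crms(
            gene,
            track,
            genes,
            genome,
            tip_min=cfg.tip_min,
            boundary_frac=cfg.boundary_frac,
            chrom_size=len(genome[gene.chrom]),
        )
    except StopIteration as exc:
        raise PrescreenError(
            f"peak stage: gene {cfg.gene_id!r} or its chromosome not found"
        ) from exc
    except Exception as exc:
        raise PrescreenError(f"peak stage: {exc}") from exc

    # 4. density and classification
    ccfg = ClassifierConfig(
        thr_low=cfg.thr_low,
        thr_high=cfg.thr_high,
        density_x_cut=cfg.density_x_cut,
        density_y_cut=cfg.density_y_cut,
        merge_window_bp=cfg.merge_window_bp,
        combine_rule=cfg.combine_rule,
        relative_threshold=cfg.relative_threshold,
    )
    profiles_out = []
    for crm in candidates:
        mask = detect_tandem_repeats(crm.sequence) if cfg.mask_repeats else None
        profiles_out.append(tfbs_density(crm, profiles, ccfg, mask))

    # 5. outputs
    _write_table(out / "markers.tsv", markers_to_frame(markers), cfg)
    _write_table(out / "tf_panel.tsv", markers_to_frame(panel), cfg)
    dens = pd.DataFrame(density_table(profiles_out))
    _write_table(out / "density.tsv", dens, cfg)
    scatter = dens[["crm_id", "density_low", "density_high"]] if len(dens) else dens
    _write_table(out / "scatter.tsv", scatter, cfg)
    write_fasta(out / "candidates.fa", [c.sequence for c in candidates])
    write_peaks_bed(
        out / "peaks.bed",
        [
            Peak(chrom=c.chrom, start=c.start, end=c.end, tip_pos=c.start, tip_value=0.0)
            for c in candidates
        ],
    )
    inputs = {
        k: _sha256(getattr(cfg, k))
        for k in ("counts", "clusters", "tf_list", "pfm", "coverage", "genes", "genome")
    }
    cfg_json = json.dumps(_config_echo(cfg), sort_keys=True)
    manifest = {
        "crmscan_version": __version__,
        "config": _config_echo(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_sha256": inputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "n_markers_pass": sum(r.passes for r in markers),
        "tf_panel": sorted(panel_names),
        "n_candidates": len(candidates),
        "n_predicted_active": sum(d.predicted_active for d in profiles_out),
        "density": profiles_out,
    }
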