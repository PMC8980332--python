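"""Synthetic inputs with known ground truth for the whole pipeline.

Every input the analysis consumes can be generated here: motif-planted
DNA sequences, peaked accessibility coverage tracks with analytic
boundary truth, gene models, and clustered negative-binomial count
matrices with planted marker genes.  Each generator returns its truth
table in the same 0-based half-open, forward-anchored coordinates the
analysis modules use, so recovery can be checked exactly.

A single integer seed drives everything; per-component substreams are
derived from it so individual inputs can be regenerated independently
and byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import ExpressionMatrix
from .motifs import (
    BASES,
    DnaSequence,
    MotifProfile,
    make_motif_profile,
    reverse_complement,
    write_fasta,
    write_jaspar_pfm,
)
from .peaks import CoverageTrack, GeneModel, write_bed12_genes, write_bedgraph


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _stream_key(stream)]))


def _stream_key(stream: str) -> int:
    return int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "big") % (2**31)


@dataclass(frozen=True)
class PeakSpec:
    """Analytic peak shape to paint onto a coverage track."""

    tip_pos: int
    tip_value: float
    half_width: int
    shape: str = "triangular"  # triangular | gaussian | plateau

    def __post_init__(self) -> None:
        if self.shape not in ("triangular", "gaussian", "plateau"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.tip_value <= 0 or self.half_width <= 0:
            raise ValueError("tip_value and half_width must be > 0")


def make_profile(consensus: str, sharpness: float = 1.0, total: int = 100,
                 motif_id: str | None = None, tf_name: str | None = None) -> MotifProfile:
    """Build a synthetic motif whose consensus is the given string.

    Each column puts ``sharpness x total`` counts on the consensus base
    and spreads the remainder evenly over the other three bases, so
    sharpness 1 is a consensus-only matrix and lower sharpness flattens
    the columns (lower information content).
    """
    if not 0 < sharpness <= 1:
        raise ValueError("sharpness must lie in (0, 1]")
    consensus = consensus.upper()
    if set(consensus) - set(BASES):
        raise ValueError(f"consensus must be over {BASES}")
    L = len(consensus)
    pfm = np.zeros((4, L))
    on = sharpness * total
    off = (1.0 - sharpness) * total / 3.0
    for j, base in enumerate(consensus):
        for i in range(4):
            pfm[i, j] = on if BASES[i] == base else off
    if np.allclose(pfm, np.round(pfm)):
        pfm = np.round(pfm).astype(int)
    return make_motif_profile(
        motif_id=motif_id or f"SYN_{consensus}",
        tf_name=tf_name or f"Tf_{consensus}",
        pfm=pfm,
    )


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def plant_sequence(
    length: int,
    sites: list[tuple[MotifProfile, int, str]],
    background_gc: float = 0.5,
    seed: int = 0,
    seq_id: str = "synthetic",
    allow_overlap: bool = False,
) -> tuple[DnaSequence, pd.DataFrame]:
    """Random-background sequence with motif consensus sites written in.

    ``sites`` are (profile, forward start, strand); a ``-`` site writes
    the reverse complement of the consensus so scanning recovers a minus
    hit at the same forward coordinates.  Returns the sequence and a
    truth table (motif_id, start, end, strand).
    """
    rng = _rng(seed, f"seq:{seq_id}")
    bases = list(random_background(length, background_gc, rng))
    placed: list[tuple[int, int]] = []
    rows = []
    for profile, pos, strand in sites:
        word = profile.consensus
        end = pos + len(word)
        if pos < 0 or end > length:
            raise ValueError(f"site at {pos} exceeds sequence bounds (length {length})")
        if not allow_overlap and any(pos < e and s < end for s, e in placed):
            raise ValueError(f"site at {pos} overlaps a previously planted site")
        written = word if strand == "+" else reverse_complement(word)
        bases[pos:end] = list(written)
        placed.append((pos, end))
        rows.append(
            {"motif_id": profile.motif_id, "start": pos, "end": end, "strand": strand}
        )
    truth = pd.DataFrame(rows, columns=["motif_id", "start", "end", "strand"])
    return DnaSequence(seq_id, "".join(bases)), truth


def analytic_boundaries(spec: PeakSpec, boundary_frac: float = 0.2) -> tuple[int, int]:
    """Closed-form positions of the outermost bases still >= frac x tip."""
    c, hw = spec.tip_pos, spec.half_width
    if spec.shape == "triangular":
        r = math.floor((1 - boundary_frac) * hw + 1e-9)
    elif spec.shape == "gaussian":
        r = math.floor(hw * math.sqrt(2.0 * math.log(1.0 / boundary_frac)))
    else:  # plateau: constant tip over [c, c + hw)
        return c, c + hw
    return c - r, c + r + 1


def shape_values(spec: PeakSpec, length: int) -> np.ndarray:
    """Evaluate one peak shape over [0, length)."""
    x = np.arange(length, dtype=float)
    c, tip, hw = spec.tip_pos, spec.tip_value, spec.half_width
    if spec.shape == "triangular":
        slope = tip / hw
        v = tip - slope * np.abs(x - c)
        return np.maximum(v, 0.0)
    if spec.shape == "gaussian":
        v = tip * np.exp(-((x - c) ** 2) / (2.0 * hw * hw))
        v[np.abs(x - c) > 6 * hw] = 0.0
        return v
    v = np.zeros(length)
    v[max(c, 0) : min(c + hw, length)] = tip
    return v


def make_coverage(
    length: int,
    specs: list[PeakSpec],
    chrom: str = "chrS",
    origin: int = 0,
    noise_sd: float = 0.0,
    tip_min: float = 20.0,
    boundary_frac: float = 0.2,
    seed: int = 0,
) -> tuple[CoverageTrack, pd.DataFrame]:
    """Sum analytic peak shapes onto a zero baseline; truth table carries
    the analytic boundary positions and a sub-threshold flag.

    Peak supports should not overlap if the truth boundaries are to be
    exact.  Gaussian noise (sd ``noise_sd``, clipped at 0) is added when
    requested; with noise the truth remains the noise-free geometry.
    """
    values = np.zeros(length)
    rows = []
    for spec in specs:
        values += shape_values(spec, length)
        s, e = analytic_boundaries(spec, boundary_frac)
        rows.append(
            {
                "chrom": chrom,
                "start": origin + s,
                "end": origin + e,
                "tip_pos": origin + spec.tip_pos,
                "tip_value": spec.tip_value,
                "shape": spec.shape,
                "subthreshold": spec.tip_value < tip_min,
            }
        )
    if noise_sd > 0:
        rng = _rng(seed, f"coverage:{chrom}")
        values = np.maximum(values + rng.normal(0.0, noise_sd, size=length), 0.0)
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "tip_pos", "tip_value", "shape", "subthreshold"],
    )
    return CoverageTrack(chrom=chrom, origin=origin, values=values), truth


@dataclass(frozen=True)
class ExpressionSpec:
    """Negative-binomial count-matrix design with planted markers.

    ``nb_dispersion`` is the overdispersion alpha in
    var = mu + alpha * mu^2; planted markers multiply the gene's mean in
    their cluster by ``fold_change``.
    """

    n_genes: int = 1000
    cluster_cells: tuple[tuple[str, int], ...] = (("MG", 100), ("Rod", 150), ("BC", 150))
    nb_mean: float = 8.0
    nb_dispersion: float = 0.5
    planted_markers: tuple[tuple[str, str, float], ...] = ()  # (gene, cluster, fold)
    n_mito_genes: int = 10
    mito_mean: float = 5.0
    n_high_mito_cells: int = 0
    n_low_complexity_cells: int = 0


def _nb_draws(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def make_expression(spec: ExpressionSpec, seed: int = 0) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Clustered NB count matrix with planted markers and mito genes.

    Named planted genes replace the tail of the default gene id list.
    Optional QC violators: cells with ~30% mitochondrial counts and
    cells expressing very few genes, appended to the first cluster.
    """
    rng = _rng(seed, "expression")
    gene_names = [f"gene{i:04d}" for i in range(spec.n_genes)]
    planted_names = []
    for g, _, _ in spec.planted_markers:
        if g not in planted_names:
            planted_names.append(g)
    for i, g in enumerate(planted_names):
        gene_names[spec.n_genes - len(planted_names) + i] = g
    mito_names = [f"mt-{i}" for i in range(spec.n_mito_genes)]
    genes = gene_names + mito_names
    gi = {g: k for k, g in enumerate(genes)}

    cells, labels = [], []
    for label, n in spec.cluster_cells:
        for k in range(n):
            cells.append(f"{label}_c{k:04d}")
            labels.append(label)

    mu = np.full((len(genes), len(cells)), spec.nb_mean)
    for name in mito_names:
        mu[gi[name], :] = spec.mito_mean
    fold_of = {}
    for g, cluster, fold in spec.planted_markers:
        fold_of[(g, cluster)] = fold
        col = np.array([lab == cluster for lab in labels])
        mu[gi[g], col] *= fold
    counts = _nb_draws(rng, mu, spec.nb_dispersion, mu.shape)

    # QC violators appended to the first cluster
    first = spec.cluster_cells[0][0]
    extra_cols = []
    for k in range(spec.n_high_mito_cells):
        col = _nb_draws(rng, np.full(len(genes), spec.nb_mean), spec.nb_dispersion, len(genes))
        total = max(int(col.sum()), 1)
        per_mito = math.ceil(0.45 * total / max(spec.n_mito_genes, 1))
        for name in mito_names:
            col[gi[name]] = per_mito  # ~30%+ of the new total is mitochondrial
        cells.append(f"{first}_himito{k}")
        labels.append(first)
        extra_cols.append(col)
    for k in range(spec.n_low_complexity_cells):
        col = np.zeros(len(genes), dtype=counts.dtype)
        keep = rng.choice(spec.n_genes, size=min(50, spec.n_genes), replace=False)
        col[keep] = 1
        cells.append(f"{first}_lowcx{k}")
        labels.append(first)
        extra_cols.append(col)
    if extra_cols:
        counts = np.hstack([counts, np.column_stack(extra_cols)])

    mat = ExpressionMatrix(
        genes=genes,
        cells=cells,
        counts=counts,
        cluster_of=dict(zip(cells, labels)),
        mito_genes=frozenset(mito_names),
    )
    truth = pd.DataFrame(
        [
            {"gene_id": g, "cluster": c, "fold_change": f}
            for (g, c), f in fold_of.items()
        ],
        columns=["gene_id", "cluster", "fold_change"],
    )
    return mat, truth


# --------------------------------------------------------------------------
# demo presets: write every file the pipeline reads, plus truth/ tables
# --------------------------------------------------------------------------

MG_TFS = ("Lhx2", "Sox9", "Nfia")
MG_MOTIF_CONSENSI = ("TAATTAGCGC", "CCATTGTTCT", "TTGGCAAGGA")
DECOY_TF = "Crx"
DECOY_CONSENSUS = "GGATTAGGCC"


def mg_demo_profiles() -> list[MotifProfile]:
    """The demo TF panel: three glia-enriched TFs plus one photoreceptor decoy."""
    profiles = [
        make_profile(c, sharpness=1.0, motif_id=f"MA{i:04d}", tf_name=tf)
        for i, (tf, c) in enumerate(zip(MG_TFS, MG_MOTIF_CONSENSI), start=1)
    ]
    profiles.append(
        make_profile(DECOY_CONSENSUS, sharpness=1.0, motif_id="MA0099", tf_name=DECOY_TF)
    )
    return profiles


def mg_demo_expression_spec() -> ExpressionSpec:
    planted = [(tf, "MG", 16.0) for tf in MG_TFS]
    planted += [(g, "MG", 16.0) for g in ("Rlbp1", "Glul", "Aqp4", "Clu")]
    planted += [(DECOY_TF, "Rod", 16.0), ("Prkca", "BC", 16.0)]
    return ExpressionSpec(planted_markers=tuple(planted))


@dataclass
class MgDemo:
    """In-memory form of the mg-demo preset (see :func:`build_mg_demo`)."""

    genome: dict[str, str]
    genes: list[GeneModel]
    track: CoverageTrack
    peak_truth: pd.DataFrame
    profiles: list[MotifProfile]
    expression: ExpressionMatrix
    marker_truth: pd.DataFrame
    site_truth: pd.DataFrame
    active_truth: pd.DataFrame
    target_gene: str = "Rlbp1"
    target_cluster: str = "MG"


def build_mg_demo(seed: int = 7) -> MgDemo:
    """A complete synthetic locus exercising the end-to-end prescreen.

    One 24 kb chromosome carries the target gene flanked by two
    neighbours.  Four accessible peaks sit in the flanking region: two
    "active" candidates densely planted with the glia TF motifs, two
    motif-free decoys; a fifth peak is sub-threshold and a sixth
    overlaps an exon.  The count matrix plants the glia TFs (and a few
    non-TF glia genes) at 16x in the MG cluster.
    """
    chrom = "chrS"
    length = 24000
    profiles = mg_demo_profiles()
    mg_profiles = profiles[:3]

    genes = [
        GeneModel("Nbr1up", chrom, "+", 1000, 3000, ((1000, 1400), (2600, 3000))),
        GeneModel(
            "Rlbp1", chrom, "+", 10000, 12000, ((10000, 10300), (11600, 12000))
        ),
        GeneModel("Nbr2dn", chrom, "+", 20000, 22000, ((20000, 20500), (21500, 22000))),
    ]

    # peaks in the flanking region [3000, 20000); half-widths chosen so the
    # analytic 20%-of-tip boundary clears the cut with a non-trivial margin
    specs = [
        PeakSpec(tip_pos=4500, tip_value=40.0, half_width=201, shape="triangular"),
        PeakSpec(tip_pos=6500, tip_value=30.0, half_width=150, shape="plateau"),
        PeakSpec(tip_pos=8600, tip_value=50.0, half_width=120, shape="gaussian"),
        PeakSpec(tip_pos=14000, tip_value=25.0, half_width=181, shape="triangular"),
        PeakSpec(tip_pos=16500, tip_value=15.0, half_width=101, shape="triangular"),
        PeakSpec(tip_pos=11800, tip_value=35.0, half_width=61, shape="triangular"),  # exonic
    ]
    track, peak_truth = make_coverage(length, specs, chrom=chrom, seed=seed)

    # plant dense glia-TF sites inside the first (triangular, [4340,4661))
    # and third (gaussian, [8385,8816)) peak intervals; the others stay
    # motif-free; 20 bp spacing keeps sites disjoint and un-merged
    sites: list[tuple[MotifProfile, int, str]] = []
    for base, n_sites, spacing in ((4350, 15, 20), (8450, 18, 20)):
        for k in range(n_sites):
            prof = mg_profiles[k % len(mg_profiles)]
            strand = "+" if k % 2 == 0 else "-"
            sites.append((prof, base + k * spacing, strand))
    seq, site_truth = plant_sequence(
        length, sites, background_gc=0.45, seed=seed, seq_id=chrom
    )
    genome = {chrom: seq.bases}

    expression, marker_truth = make_expression(mg_demo_expression_spec(), seed=seed)

    active_truth = pd.DataFrame(
        [
            {"tip_pos": 4500, "active": True},
            {"tip_pos": 6500, "active": False},
            {"tip_pos": 8600, "active": True},
            {"tip_pos": 14000, "active": False},
        ]
    )
    return MgDemo(
        genome=genome,
        genes=genes,
        track=track,
        peak_truth=peak_truth,
        profiles=profiles,
        expression=expression,
        marker_truth=marker_truth,
        site_truth=site_truth,
        active_truth=active_truth,
    )


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_mg_demo(outdir, seed: int = 7) -> MgDemo:
    """Write the mg-demo preset files (and truth/) under ``outdir``."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    demo = build_mg_demo(seed=seed)

    write_fasta(out / "genome.fa", [DnaSequence(c, s) for c, s in demo.genome.items()])
    write_bed12_genes(out / "genes.bed", demo.genes)
    write_bedgraph(out / "coverage.bedgraph", demo.track)
    write_jaspar_pfm(out / "motifs.jaspar", demo.profiles)
    counts = pd.DataFrame(
        demo.expression.counts, index=demo.expression.genes, columns=demo.expression.cells
    )
    counts.index.name = "gene_id"
    counts.to_csv(out / "counts.tsv", sep="\t")
    clusters = pd.DataFrame(
        {
            "cell_id": demo.expression.cells,
            "cluster": [demo.expression.cluster_of[c] for c in demo.expression.cells],
        }
    )
    _write_tsv(out / "clusters.tsv", clusters)
    tf_rows = pd.DataFrame({"tf": list(MG_TFS) + [DECOY_TF]})
    tf_rows.to_csv(out / "tf_list.tsv", sep="\t", index=False, header=False)

    _write_tsv(out / "truth" / "sites.tsv", demo.site_truth)
    _write_tsv(out / "truth" / "peaks.tsv", demo.peak_truth)
    _write_tsv(out / "truth" / "markers.tsv", demo.marker_truth)
    _write_tsv(out / "truth" / "active_crms.tsv", demo.active_truth)
    manifest = {"preset": "mg-demo", "seed": seed, "target_gene": demo.target_gene,
                "target_cluster": demo.target_cluster}
    (out / "preset.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return demo


def write_peaks_demo(outdir, seed: int = 7) -> None:
    """Coverage + gene models + genome only (peak-calling practice set)."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    demo = build_mg_demo(seed=seed)
    write_fasta(out / "genome.fa", [DnaSequence(c, s) for c, s in demo.genome.items()])
    write_bed12_genes(out / "genes.bed", demo.genes)
    write_bedgraph(out / "coverage.bedgraph", demo.track)
    _write_tsv(out / "truth" / "peaks.tsv", demo.peak_truth)


def write_markers_demo(outdir, seed: int = 7) -> None:
    """Count matrix + clusters + TF list only."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    mat, truth = make_expression(mg_demo_expression_spec(), seed=seed)
    counts = pd.DataFrame(mat.counts, index=mat.genes, columns=mat.cells)
    counts.index.name = "gene_id"
    counts.to_csv(out / "counts.tsv", sep="\t")
    clusters = pd.DataFrame(
        {"cell_id": mat.cells, "cluster": [mat.cluster_of[c] for c in mat.cells]}
    )
    _write_tsv(out / "clusters.tsv", clusters)
    pd.DataFrame({"tf": list(MG_TFS) + [DECOY_TF]}).to_csv(
        out / "tf_list.tsv", sep="\t", index=False, header=False
    )
    _write_tsv(out / "truth" / "markers.tsv", truth)


def build_stitch_demo(seed: int = 7):
    """A locus for the stitching designer: retina-stage peak sets of which
    some overlap brain peaks and one is exonic.

    Returns (genome, genes, stage_sets, brain_set, expected_kept_intervals).
    """
    from .stitch import StagePeakSet
    from .peaks import Peak

    chrom = "chrA"
    length = 12000
    rng = _rng(seed, "stitch-genome")
    genome = {chrom: random_background(length, 0.45, rng)}
    genes = [
        GeneModel("Gad1", chrom, "+", 5000, 6000, ((5000, 5200), (5800, 6000))),
    ]

    def pk(s, e, tip):
        return Peak(chrom=chrom, start=s, end=e, tip_pos=(s + e) // 2, tip_value=tip)

    retina_p1 = StagePeakSet("retina_P1", (pk(1000, 1300, 40), pk(3000, 3200, 25)))
    retina_p7 = StagePeakSet("retina_P7", (pk(1100, 1400, 35), pk(5100, 5350, 30)))
    retina_8wk = StagePeakSet("retina_8wk", (pk(7000, 7400, 50), pk(9000, 9250, 28)))
    brain = StagePeakSet("brain", (pk(3100, 3400, 22), pk(9100, 9200, 31)))
    # union: [1000,1400) [3000,3200) [5100,5350) [7000,7400) [9000,9250)
    # brain overlap removes [3000,3200) and [9000,9250);
    # exon overlap removes [5100,5350) (exon [5000,5200))
    expected_kept = [(1000, 1400), (7000, 7400)]
    return genome, genes, [retina_p1, retina_p7, retina_8wk], brain, expected_kept


def write_stitch_demo(outdir, seed: int = 7) -> None:
    from .peaks import write_peaks_bed

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    genome, genes, stages, brain, expected = build_stitch_demo(seed=seed)
    write_fasta(out / "genome.fa", [DnaSequence(c, s) for c, s in genome.items()])
    write_bed12_genes(out / "genes.bed", genes)
    for s in stages:
        write_peaks_bed(out / f"{s.label}.bed", list(s.peaks))
    write_peaks_bed(out / "brain.bed", list(brain.peaks))
    _write_tsv(
        out / "truth" / "kept_intervals.tsv",
        pd.DataFrame(expected, columns=["start", "end"]),
    )


PRESETS = {
    "mg-demo": write_mg_demo,
    "peaks-demo": write_peaks_demo,
    "markers-demo": write_markers_demo,
    "stitch-demo": write_stitch_demo,
}


def simulate_preset(preset: str, outdir, seed: int = 7) -> None:
    try:
        writer = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    writer(outdir, seed=seed)
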