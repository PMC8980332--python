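"""Nominate putative CRMs from chromatin-accessibility coverage tracks.

Candidates are accessibility peaks in the region flanking a gene of
interest, bounded by the neighbouring gene bodies.  A peak is emitted
when its tip (maximum per-base signal) reaches a floor (default 20);
its borders are placed at the outermost contiguous positions whose
signal still reaches a fraction of the tip (default 20%).  Peaks that
overlap any exon by at least one base are excluded — intronic and
intergenic peaks remain eligible, since known active modules can sit in
the intron of an unrelated gene.

Coverage is read from bedGraph or wiggle (fixedStep/variableStep) text;
positions not covered by any interval read as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import CRMCandidate
from .motifs import DnaSequence

# sentinel for "no downstream neighbour and no chromosome size given";
# callers clip regions to the coverage track extent anyway
UNBOUNDED = 2**62


class CoverageFormatError(ValueError):
    """Raised for malformed bedGraph/wiggle input."""


@dataclass
class CoverageTrack:
    """Dense per-base signal for one chromosome, starting at ``origin``."""

    chrom: str
    origin: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.origin + self.values.size


@dataclass(frozen=True)
class Peak:
    """A called accessible region with its summit position and value."""

    chrom: str
    start: int
    end: int
    tip_pos: int
    tip_value: float
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start <= self.tip_pos < self.end:
            raise ValueError("tip_pos must lie in [start, end)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int, min_bp: int = 1) -> bool:
        return min(self.end, end) - max(self.start, start) >= min_bp


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its exon structure (0-based, half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, disjoint, within the gene body"
                )
            prev_end = e


def read_coverage(path) -> list[CoverageTrack]:
    """Read bedGraph or wiggle coverage into dense per-chromosome tracks.

    Dialect is detected per line: ``fixedStep``/``variableStep``
    declarations switch to wiggle mode, 4-column lines are bedGraph.
    Intervals may arrive unsorted but must not overlap.  Gaps between
    covered intervals read as 0.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # None | ("fixed", chrom, next_start, step, span) | ("var", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if fields[0] == "fixedStep":
                kv = dict(f.split("=", 1) for f in fields[1:])
                mode = (
                    "fixed",
                    kv["chrom"],
                    int(kv["start"]) - 1,  # wiggle is 1-based
                    int(kv.get("step", 1)),
                    int(kv.get("span", 1)),
                )
                continue
            if fields[0] == "variableStep":
                kv = dict(f.split("=", 1) for f in fields[1:])
                mode = ("var", kv["chrom"], int(kv.get("span", 1)))
                continue
            if mode is not None and mode[0] == "fixed" and len(fields) == 1:
                _, chrom, start, step, span = mode
                value = float(fields[0])
                _add_interval(intervals, chrom, start, start + span, value, path, lineno)
                mode = ("fixed", chrom, start + step, step, span)
                continue
            if mode is not None and mode[0] == "var" and len(fields) == 2:
                pos = int(fields[0]) - 1
                value = float(fields[1])
                _add_interval(intervals, mode[1], pos, pos + mode[2], value, path, lineno)
                continue
            if len(fields) == 4:
                mode = None
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                _add_interval(intervals, chrom, s, e, v, path, lineno)
                continue
            raise CoverageFormatError(f"{path}:{lineno}: unrecognised line: {line!r}")

    tracks: list[CoverageTrack] = []
    for chrom in sorted(intervals):
        ivs = sorted(intervals[chrom])
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise CoverageFormatError(
                    f"{path}: overlapping intervals on {chrom} at {s2}"
                )
        origin = ivs[0][0]
        values = np.zeros(ivs[-1][1] - origin)
        for s, e, v in ivs:
            values[s - origin : e - origin] = v
        tracks.append(CoverageTrack(chrom=chrom, origin=origin, values=values))
    return tracks


def _add_interval(intervals, chrom, start, end, value, path, lineno) -> None:
    if value < 0:
        raise CoverageFormatError(f"{path}:{lineno}: negative coverage value {value}")
    if end <= start:
        raise CoverageFormatError(f"{path}:{lineno}: empty interval")
    intervals.setdefault(chrom, []).append((start, end, value))


def flanking_region(
    gene: GeneModel,
    all_genes: list[GeneModel],
    chrom_size: int | None = None,
) -> tuple[int, int]:
    """Region from the nearest upstream gene's end to the nearest
    downstream gene's start, including the query gene's own body.

    With no upstream neighbour the region starts at 0; with no
    downstream neighbour it ends at ``chrom_size`` when given, else at a
    large sentinel (callers clip to the coverage track).  A neighbour
    overlapping the gene body clips that side to zero extension, with a
    warning.
    """
    if gene not in all_genes and gene.gene_id not in {g.gene_id for g in all_genes}:
        raise KeyError(f"gene {gene.gene_id} not found in the gene set")
    left = 0
    right = chrom_size if chrom_size is not None else UNBOUNDED
    for other in all_genes:
        if other.chrom != gene.chrom or other.gene_id == gene.gene_id:
            continue
        if other.tx_start < gene.tx_start:
            if other.tx_end > gene.tx_start:
                warnings.warn(
                    f"gene {other.gene_id} overlaps {gene.gene_id} upstream; "
                    "flanking region clipped to the gene start"
                )
                left = max(left, gene.tx_start)
            else:
                left = max(left, other.tx_end)
        elif other.tx_start >= gene.tx_start and other.tx_start < gene.tx_end:
            warnings.warn(
                f"gene {other.gene_id} overlaps {gene.gene_id} downstream; "
                "flanking region clipped to the gene end"
            )
            right = min(right, gene.tx_end)
        else:
            right = min(right, other.tx_start)
    return left, right


def call_peaks(
    track: CoverageTrack,
    region: tuple[int, int] | None = None,
    tip_min: float = 20.0,
    boundary_frac: float = 0.2,
) -> list[Peak]:
    """Call peaks whose tip reaches ``tip_min``, with borders at the
    outermost contiguous positions still >= ``boundary_frac`` x tip.

    Overlapping extents from distinct local maxima are merged, keeping
    the higher tip.  Plateau summits report their leftmost position.
    A region outside the track yields an empty list.
    """
    if not 0 < boundary_frac < 1:
        raise ValueError("boundary_frac must lie in (0, 1)")
    if tip_min <= 0:
        raise ValueError("tip_min must be > 0")
    lo, hi = region if region is not None else (track.origin, track.end)
    lo = max(lo, track.origin)
    hi = min(hi, track.end)
    if hi <= lo:
        return []
    v = track.values[lo - track.origin : hi - track.origin]
    n = v.size

    # leftmost positions of plateaus that are local maxima
    summits: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and v[i] >= tip_min and v[i] > 0:
            summits.append(i)
        i = j + 1

    raw: list[Peak] = []
    for s in summits:
        cut = boundary_frac * v[s]
        a = s
        while a > 0 and v[a - 1] >= cut:
            a -= 1
        b = s
        while b + 1 < n and v[b + 1] >= cut:
            b += 1
        raw.append(
            Peak(
                chrom=track.chrom,
                start=lo + a,
                end=lo + b + 1,
                tip_pos=lo + s,
                tip_value=float(v[s]),
            )
        )
    raw.sort(key=lambda p: (p.start, p.end))
    merged: list[Peak] = []
    for p in raw:
        if merged and p.start < merged[-1].end:
            q = merged[-1]
            if p.tip_value > q.tip_value or (
                p.tip_value == q.tip_value and p.tip_pos < q.tip_pos
            ):
                tip_pos, tip_value = p.tip_pos, p.tip_value
            else:
                tip_pos, tip_value = q.tip_pos, q.tip_value
            merged[-1] = Peak(
                chrom=p.chrom,
                start=q.start,
                end=max(q.end, p.end),
                tip_pos=tip_pos,
                tip_value=tip_value,
            )
        else:
            merged.append(p)
    return merged


def exclude_exonic(peaks: list[Peak], gene_models: list[GeneModel]) -> list[Peak]:
    """Drop any peak sharing >= 1 bp with any exon of any gene."""
    kept = []
    for p in peaks:
        exonic = any(
            p.overlaps(es, ee)
            for g in gene_models
            if g.chrom == p.chrom
            for es, ee in g.exons
        )
        if not exonic:
            kept.append(p)
    return kept


def extract_sequence(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    if not 0 <= start < end <= len(seq):
        raise ValueError(f"{chrom}:{start}-{end} outside genome sequence")
    return seq[start:end]


def nominate_crms(
    gene: GeneModel,
    track: CoverageTrack,
    gene_models: list[GeneModel],
    genome: dict[str, str],
    tip_min: float = 20.0,
    boundary_frac: float = 0.2,
    chrom_size: int | None = None,
) -> list[CRMCandidate]:
    """Flanking region -> peak calling -> exon exclusion -> sequence extraction.

    Candidates are named ``<gene>_<ordinal>`` in genomic order.
    """
    region = flanking_region(gene, gene_models, chrom_size=chrom_size)
    peaks = call_peaks(track, region, tip_min=tip_min, boundary_frac=boundary_frac)
    peaks = exclude_exonic(peaks, gene_models)
    candidates = []
    for i, p in enumerate(peaks, 1):
        bases = extract_sequence(genome, p.chrom, p.start, p.end)
        crm_id = f"{gene.gene_id}_{i}"
        candidates.append(
            CRMCandidate(
                crm_id=crm_id,
                sequence=DnaSequence(crm_id, bases),
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                source_gene=gene.gene_id,
            )
        )
    return candidates


def read_bed12_genes(path) -> list[GeneModel]:
    """Read gene models with exon structure from BED12."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    return genes


def write_bed12_genes(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Write a track as run-length-compressed bedGraph, omitting zeros."""
    with open(path, "w") as fh:
        v = track.values
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[j + 1] == v[i]:
                j += 1
            if v[i] != 0:
                fh.write(
                    f"{track.chrom}\t{track.origin + i}\t{track.origin + j + 1}\t{v[i]:g}\n"
                )
            i = j + 1


def write_peaks_bed(path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.tip_value:g}\t.\n"
            )


def read_peaks_bed(path, label: str | None = None) -> list[Peak]:
    """Read BED >= 3 columns as peaks; score column (5) becomes tip_value."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            tip = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    tip_pos=start,
                    tip_value=tip,
                    sources=(label,) if label else (),
                )
            )
    return peaks
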