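"""TFBS density scoring and quadrant classification of CRM candidates.

The prescreen statistic: scan a candidate CRM with a panel of
cell-type-enriched TF motifs at 80% relative score, keep hits above two
raw log-odds cuts (default > 10 and > 11), collapse hits whose starts
fall within a short window (default 5 bp) into single "TFBS counts",
and normalise by candidate length to sites per 100 bp.  Candidates
whose densities exceed both cuts (> 1.7 per 100 bp at the lenient score
cut and > 1 per 100 bp at the strict one) fall in quadrant A2 of the
two-threshold density plot and are predicted active.

Long tandem repeats (e.g. CTCCCT repeats or (AC)n microsatellites) can
inflate apparent site counts; hits fully contained in detected repeat
intervals are skipped before counting, while the density denominator
remains the full candidate length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import DnaSequence, MotifHit, MotifProfile, scan_sequence


@dataclass(frozen=True)
class CRMCandidate:
    """A candidate cis-regulatory module: a sequence, optionally placed on a genome."""

    crm_id: str
    sequence: DnaSequence
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    source_gene: str | None = None
    source_cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if self.end - self.start != len(self.sequence):
                raise ValueError(
                    f"{self.crm_id}: interval length {self.end - self.start} "
                    f"!= sequence length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class RepeatInterval:
    start: int
    end: int
    unit_length: int
    copies: int


@dataclass(frozen=True)
class RepeatMask:
    """Non-overlapping, sorted half-open intervals flagged as tandem repeats."""

    intervals: tuple[RepeatInterval, ...] = ()

    def __post_init__(self) -> None:
        ivs = self.intervals
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError("repeat mask intervals must be sorted and disjoint")

    def contains_interval(self, start: int, end: int) -> bool:
        """True if [start, end) lies fully inside some masked interval."""
        return any(iv.start <= start and end <= iv.end for iv in self.intervals)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the two-axis density classifier.

    ``thr_low``/``thr_high`` are raw log-odds score cuts defining the
    x and y axes; ``density_x_cut``/``density_y_cut`` are the per-100-bp
    density cuts; both density comparisons are strict (>).
    """

    thr_low: float = 10.0
    thr_high: float = 11.0
    density_x_cut: float = 1.7
    density_y_cut: float = 1.0
    merge_window_bp: int = 5
    combine_rule: str = "AND"
    relative_threshold: float = 0.80
    merge_chaining: str = "anchor"

    def __post_init__(self) -> None:
        if self.thr_high < self.thr_low:
            raise ValueError("thr_high must be >= thr_low")
        if self.density_x_cut <= 0 or self.density_y_cut <= 0:
            raise ValueError("density cuts must be > 0")
        if self.combine_rule not in ("AND", "OR"):
            raise ValueError("combine_rule must be AND or OR")
        if self.merge_chaining not in ("anchor", "neighbor"):
            raise ValueError("merge_chaining must be anchor or neighbor")


@dataclass(frozen=True)
class DensityProfile:
    """Per-candidate TFBS densities at the two score cuts, plus the call."""

    crm_id: str
    length_bp: int
    count_low: int
    count_high: int
    density_low: float
    density_high: float
    quadrant: str
    predicted_active: bool


def detect_tandem_repeats(
    seq: DnaSequence | str,
    max_unit: int = 6,
    min_copies: int = 3,
    min_total_len: int = 12,
) -> RepeatMask:
    """Find maximal short-period tandem repeats (unit <= ``max_unit`` bp).

    An interval qualifies when a unit repeats >= ``min_copies`` full
    times and the repeated stretch spans >= ``min_total_len`` bp.
    Overlapping detections for different unit lengths are merged into
    maximal intervals.
    """
    if max_unit <= 0 or max_unit > 10 or min_copies <= 0 or min_total_len <= 0:
        raise ValueError("repeat-detection parameters must be positive, max_unit <= 10")
    s = seq.bases if isinstance(seq, DnaSequence) else seq.upper()
    n = len(s)
    found: list[RepeatInterval] = []
    for u in range(1, min(max_unit, n) + 1):
        i = 0
        while i + u < n:
            if s[i] != s[i + u]:
                i += 1
                continue
            # extend the period-u match run starting at i
            j = i + u
            while j < n and s[j] == s[j - u]:
                j += 1
            span = j - i  # [i, j) satisfies s[k] == s[k-u]
            copies = span // u
            if copies >= min_copies and span >= min_total_len:
                found.append(RepeatInterval(i, j, u, copies))
            i = j - u + 1
    if not found:
        return RepeatMask()
    found.sort(key=lambda r: (r.start, r.end))
    merged: list[RepeatInterval] = [found[0]]
    for r in found[1:]:
        last = merged[-1]
        if r.start <= last.end:
            start, end = last.start, max(last.end, r.end)
            unit = min(last.unit_length, r.unit_length)
            merged[-1] = RepeatInterval(start, end, unit, (end - start) // unit)
        else:
            merged.append(r)
    return RepeatMask(tuple(merged))


def merge_hits(
    hits: list[MotifHit],
    merge_window_bp: int = 5,
    chaining: str = "anchor",
) -> int:
    """Collapse nearby hits into single TFBS counts; returns the count.

    Hits are pooled across motifs and strands and sorted by start.  With
    ``anchor`` chaining (default), a hit joins the open cluster when its
    start lies within ``merge_window_bp`` (inclusive) of the cluster's
    first hit; with ``neighbor`` chaining the distance is measured to the
    previous hit.  Anchor chaining makes the count independent of how
    far a dense run stretches.
    """
    if merge_window_bp < 0:
        raise ValueError("merge_window_bp must be >= 0")
    if chaining not in ("anchor", "neighbor"):
        raise ValueError("chaining must be anchor or neighbor")
    starts = sorted(h.start for h in hits)
    count = 0
    ref = None
    for s in starts:
        if ref is None or s - ref > merge_window_bp:
            count += 1
            ref = s
        elif chaining == "neighbor":
            ref = s
    return count


def tfbs_density(
    crm: CRMCandidate,
    profiles: list[MotifProfile],
    cfg: ClassifierConfig = ClassifierConfig(),
    mask: RepeatMask | None = None,
) -> DensityProfile:
    """Compute the two-threshold TFBS density statistic for one candidate.

    Hits fully inside a repeat-mask interval are dropped; the density
    denominator stays the full candidate length (masking removes hits,
    not sequence).
    """
    length = len(crm.sequence)
    if length == 0:
        raise ValueError(f"{crm.crm_id}: zero-length sequence")
    if not profiles:
        raise ValueError("profile list is empty")
    hits = scan_sequence(crm.sequence, profiles, cfg.relative_threshold)
    if mask is not None and mask.intervals:
        hits = [h for h in hits if not mask.contains_interval(h.start, h.end)]
    low = [h for h in hits if h.raw_score > cfg.thr_low]
    high = [h for h in hits if h.raw_score > cfg.thr_high]
    count_low = merge_hits(low, cfg.merge_window_bp, cfg.merge_chaining)
    count_high = merge_hits(high, cfg.merge_window_bp, cfg.merge_chaining)
    density_low = count_low / length * 100.0
    density_high = count_high / length * 100.0
    quadrant, active = _classify_densities(density_low, density_high, cfg)
    return DensityProfile(
        crm_id=crm.crm_id,
        length_bp=length,
        count_low=count_low,
        count_high=count_high,
        density_low=density_low,
        density_high=density_high,
        quadrant=quadrant,
        predicted_active=active,
    )


def _classify_densities(
    density_low: float, density_high: float, cfg: ClassifierConfig
) -> tuple[str, bool]:
    x = density_low > cfg.density_x_cut
    y = density_high > cfg.density_y_cut
    # Quadrant labels: A2 is the doubly-above region (predicted active
    # under AND); the other three follow a fixed convention:
    # A1 above only in y, A3 above only in x, A4 below both.
    if x and y:
        quadrant = "A2"
    elif y:
        quadrant = "A1"
    elif x:
        quadrant = "A3"
    else:
        quadrant = "A4"
    active = (x and y) if cfg.combine_rule == "AND" else (x or y)
    return quadrant, active


def classify(dp: DensityProfile, cfg: ClassifierConfig) -> DensityProfile:
    """Re-assign quadrant/active call on an existing density profile.

    Points exactly on a cut line are not above it (strict inequality).
    """
    quadrant, active = _classify_densities(dp.density_low, dp.density_high, cfg)
    return DensityProfile(
        crm_id=dp.crm_id,
        length_bp=dp.length_bp,
        count_low=dp.count_low,
        count_high=dp.count_high,
        density_low=dp.density_low,
        density_high=dp.density_high,
        quadrant=quadrant,
        predicted_active=active,
    )


def density_table(profiles: list[DensityProfile]) -> list[dict]:
    return [
        {
            "crm_id": d.crm_id,
            "length_bp": d.length_bp,
            "count_low": d.count_low,
            "count_high": d.count_high,
            "density_low": d.density_low,
            "density_high": d.density_high,
            "quadrant": d.quadrant,
            "predicted_active": d.predicted_active,
        }
        for d in profiles
    ]
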