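"""Design of synthetic "stitched" CRMs from accessibility peaks.

Accessible regions flanking a cell-type-enriched gene are gathered
across developmental stages, peaks also accessible in a second tissue
are rejected (to keep only tissue-specific elements), exonic peaks are
excluded upstream, and the survivors are concatenated in ascending
genomic order on the forward strand into one synthetic regulatory
sequence.  The construct must fit an AAV capsid: stitched CRM + cargo
ORF + vector overhead <= ~4.7 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .motifs import DnaSequence
from .peaks import Peak, extract_sequence

AAV_PACKAGING_LIMIT_BP = 4700


@dataclass(frozen=True)
class StagePeakSet:
    """Peaks called on one track (e.g. one developmental stage or tissue)."""

    label: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        ps = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))
        for a, b in zip(ps, ps[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"{self.label}: overlapping peaks within one set")
        object.__setattr__(self, "peaks", tuple(ps))


@dataclass(frozen=True)
class Budget:
    cargo_bp: int
    overhead_bp: int
    limit_bp: int = AAV_PACKAGING_LIMIT_BP

    def fits(self, crm_bp: int) -> bool:
        return crm_bp + self.cargo_bp + self.overhead_bp <= self.limit_bp


@dataclass(frozen=True)
class StitchedCRM:
    """Ordered component peaks concatenated into one synthetic sequence."""

    name: str
    components: tuple[tuple[str, Peak, str], ...]  # (source label, peak, sequence)
    sequence: DnaSequence
    budget: Budget

    @property
    def total_bp(self) -> int:
        return len(self.sequence)

    @property
    def fits(self) -> bool:
        return self.budget.fits(self.total_bp)


def union_stage_peaks(sets: list[StagePeakSet]) -> list[Peak]:
    """Interval union of peaks across stage sets.

    Overlapping peaks from different stages merge into one interval; the
    higher tip is retained and provenance labels are concatenated.
    """
    pool = []
    for s in sets:
        for p in s.peaks:
            pool.append(replace(p, sources=p.sources or (s.label,)))
    pool.sort(key=lambda p: (p.chrom, p.start, p.end))
    merged: list[Peak] = []
    for p in pool:
        last = merged[-1] if merged else None
        if last is not None and p.chrom == last.chrom and p.start < last.end:
            if p.tip_value > last.tip_value:
                tip_pos, tip_value = p.tip_pos, p.tip_value
            else:
                tip_pos, tip_value = last.tip_pos, last.tip_value
            merged[-1] = Peak(
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, p.end),
                tip_pos=tip_pos,
                tip_value=tip_value,
                sources=last.sources + tuple(x for x in p.sources if x not in last.sources),
            )
        else:
            merged.append(p)
    return merged


def tissue_specific_filter(
    candidates: list[Peak],
    other_tissue: StagePeakSet | None,
    min_overlap_bp: int = 1,
) -> list[Peak]:
    """Reject candidates sharing >= ``min_overlap_bp`` with any peak of the
    other tissue; with no other-tissue peaks all candidates pass (warned)."""
    if other_tissue is None or not other_tissue.peaks:
        warnings.warn("no other-tissue peaks supplied; specificity filtering skipped")
        return list(candidates)
    kept = []
    for p in candidates:
        shared = any(
            p.chrom == q.chrom and p.overlaps(q.start, q.end, min_overlap_bp)
            for q in other_tissue.peaks
        )
        if not shared:
            kept.append(p)
    return kept


def stitch(
    peaks: list[Peak],
    genome: dict[str, str],
    name: str,
    cargo_bp: int = 0,
    overhead_bp: int = 0,
    limit_bp: int = AAV_PACKAGING_LIMIT_BP,
    spacer: str = "",
) -> StitchedCRM:
    """Concatenate peak sequences (forward strand, ascending genomic start)
    into one synthetic CRM and account for the AAV packaging budget.

    Input order does not matter (peaks are sorted internally), but
    overlapping peaks are an error — take the interval union first.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"{name}: peaks {a.start}-{a.end} and {b.start}-{b.end} overlap; "
                "run union_stage_peaks first"
            )
    components = []
    parts = []
    for p in ordered:
        seq = extract_sequence(genome, p.chrom, p.start, p.end)
        label = ",".join(p.sources) if p.sources else ""
        components.append((label, p, seq))
        parts.append(seq)
    sequence = DnaSequence(name, spacer.join(parts))
    budget = Budget(cargo_bp=cargo_bp, overhead_bp=overhead_bp, limit_bp=limit_bp)
    return StitchedCRM(
        name=name,
        components=tuple(components),
        sequence=sequence,
        budget=budget,
    )


def component_table(crm: StitchedCRM) -> list[dict]:
    rows = []
    for label, p, seq in crm.components:
        rows.append(
            {
                "name": crm.name,
                "sources": label,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "length": len(seq),
            }
        )
    return rows


def budget_report(crm: StitchedCRM) -> dict:
    b = crm.budget
    return {
        "name": crm.name,
        "crm_bp": crm.total_bp,
        "cargo_bp": b.cargo_bp,
        "overhead_bp": b.overhead_bp,
        "total_bp": crm.total_bp + b.cargo_bp + b.overhead_bp,
        "limit_bp": b.limit_bp,
        "fits": crm.fits,
    }
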