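"""Position weight matrix construction and double-strand motif scanning.

A transcription factor's binding preference is represented by a position
frequency matrix (PFM, base counts per motif column), converted to a
log-odds position weight matrix (PWM) against a background base
distribution.  Scanning slides every motif over both strands of a DNA
sequence and reports windows whose score, rescaled to [0, 1] between the
matrix's minimum and maximum attainable scores (the "relative score"),
meets a threshold.  The default 0.80 relative threshold matches the
common web-scanner convention for nominating candidate binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif file cannot be interpreted as JASPAR-style PFMs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    Lowercase input is upcased on construction; any other character is
    rejected.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        up = self.bases.upper()
        bad = set(up) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class MotifProfile:
    """A TF binding profile: integer PFM plus derived log-odds PWM.

    ``pfm`` and ``pwm`` are 4 x L arrays with rows in A, C, G, T order.
    ``score_min``/``score_max`` are the column-wise minimum/maximum PWM
    sums; ``score_max`` is attained exactly by the consensus window.
    """

    motif_id: str
    tf_name: str
    pfm: np.ndarray
    pwm: np.ndarray
    pseudocount: float
    background: tuple[float, float, float, float]
    score_min: float
    score_max: float

    def __post_init__(self) -> None:
        if self.pfm.shape[0] != 4 or self.pfm.shape != self.pwm.shape:
            raise ValueError("pfm and pwm must both be 4 x L")
        if np.any(self.pfm < 0):
            raise ValueError(f"motif {self.motif_id}: negative PFM count")
        if np.any(self.pfm.sum(axis=0) <= 0):
            raise ValueError(
                f"motif {self.motif_id}: a PFM column has no positive count"
            )
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) <= 0:
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.pwm, axis=0))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, anchored to forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the scanned sequence's
    forward strand regardless of ``strand``; ``raw_score`` is the
    log-odds sum (the web scanner's "score" column) and
    ``relative_score`` its rescaling to [0, 1].
    """

    motif_id: str
    tf_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    raw_score: float
    relative_score: float

    def sort_key(self) -> tuple:
        return (self.start, self.motif_id, self.strand)


def pfm_to_pwm(
    pfm: np.ndarray,
    pseudocount: float = 1.0,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> tuple[np.ndarray, float, float]:
    """Convert a count matrix to a log2-odds PWM with score bounds.

    Each column j and base b scores
    ``log2((pfm[b,j] + pseudocount * bg[b]) / (colsum_j + pseudocount) / bg[b])``,
    i.e. the pseudocount is distributed across bases by the background.
    Returns ``(pwm, score_min, score_max)`` where the bounds are the
    sums of per-column minima and maxima.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("pfm must be a 4 x L array")
    bg = np.asarray(background, dtype=float).reshape(4, 1)
    colsum = pfm.sum(axis=0, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("every PFM column needs at least one positive count")
    pwm = np.log2((pfm + pseudocount * bg) / (colsum + pseudocount) / bg)
    # sequential left-to-right sums so the bounds are attained bit-exactly
    # by window scores accumulated in the same order
    score_min = 0.0
    score_max = 0.0
    for j in range(pwm.shape[1]):
        score_min += float(pwm[:, j].min())
        score_max += float(pwm[:, j].max())
    return pwm, score_min, score_max


def make_motif_profile(
    motif_id: str,
    tf_name: str,
    pfm: np.ndarray,
    pseudocount: float = 1.0,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> MotifProfile:
    pfm = np.asarray(pfm)
    pwm, lo, hi = pfm_to_pwm(pfm, pseudocount=pseudocount, background=background)
    return MotifProfile(
        motif_id=motif_id,
        tf_name=tf_name,
        pfm=pfm,
        pwm=pwm,
        pseudocount=pseudocount,
        background=tuple(background),
        score_min=lo,
        score_max=hi,
    )


def load_jaspar_pfm(
    path,
    pseudocount: float = 1.0,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> list[MotifProfile]:
    """Read JASPAR raw-PFM text (">ID NAME" headers, bracketed A/C/G/T rows).

    File order is preserved.  Malformed records raise :class:`MotifParseError`.
    """
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
    except OSError:
        raise
    except Exception as exc:  # the parser raises bare Exception for bad rows
        raise MotifParseError(f"{path}: not valid JASPAR PFM text ({exc})") from exc
    profiles: list[MotifProfile] = []
    for m in parsed:
        pfm = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        if np.any(pfm.sum(axis=0) <= 0):
            raise MotifParseError(
                f"{path}: motif {m.matrix_id or m.name}: column with zero total count"
            )
        if np.allclose(pfm, np.round(pfm)):
            pfm = np.round(pfm).astype(int)
        profiles.append(
            make_motif_profile(
                motif_id=m.matrix_id or m.name,
                tf_name=m.name or m.matrix_id,
                pfm=pfm,
                pseudocount=pseudocount,
                background=background,
            )
        )
    if not profiles:
        raise MotifParseError(f"{path}: no motifs found")
    return profiles


def write_jaspar_pfm(path, profiles: list[MotifProfile]) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f">{p.motif_id} {p.tf_name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(str(int(c)) for c in p.pfm[i])
                fh.write(f"{b} [ {row} ]\n")


def score_window(profile: MotifProfile, window: str, strand: str = "+") -> tuple[float, float]:
    """Score one window of motif length; returns (raw, relative) scores.

    A ``-`` strand hit is scored on the reverse complement of the
    forward-strand window.  An ``N`` base contributes the column minimum,
    so ambiguity can only lose hits, never create them.
    """
    if len(window) != profile.length:
        raise ValueError(
            f"window length {len(window)} != motif length {profile.length}"
        )
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    read = window.upper() if strand == "+" else reverse_complement(window.upper())
    pwm = profile.pwm
    colmin = pwm.min(axis=0)
    raw = 0.0
    for j, base in enumerate(read):
        idx = BASE_INDEX.get(base)
        raw += colmin[j] if idx is None else pwm[idx, j]
    span = profile.score_max - profile.score_min
    rel = (raw - profile.score_min) / span if span > 0 else 1.0
    return raw, rel


def scan_sequence(
    seq: DnaSequence,
    profiles: list[MotifProfile],
    relative_threshold: float = 0.80,
) -> list[MotifHit]:
    """Report every window on both strands with relative score >= threshold.

    Hits are anchored to forward-strand coordinates and sorted by
    (start, motif_id, strand).  A sequence shorter than every motif
    yields an empty list.
    """
    if not profiles:
        raise ValueError("profile list is empty")
    if not 0.0 <= relative_threshold <= 1.0:
        raise ValueError("relative_threshold must lie in [0, 1]")
    bases = seq.bases
    n = len(bases)
    # integer-encode once; N -> -1 sentinel
    enc = np.full(n, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        enc[np.frombuffer(bases.encode(), dtype=np.uint8) == ord(b)] = i

    hits: list[MotifHit] = []
    for p in profiles:
        L = p.length
        if L > n:
            continue
        pwm = p.pwm
        colmin = pwm.min(axis=0)
        span = p.score_max - p.score_min
        # scoring matrices with an extra row for N (column minimum);
        # the reverse matrix complements the base (reversed rows)
        fwd = np.vstack([pwm, colmin])
        rev = np.vstack([pwm[::-1, :], colmin])
        idx = np.lib.stride_tricks.sliding_window_view(enc, L)  # (n-L+1, L)
        # accumulate in motif-column order (left-to-right along the strand's
        # reading) so scores are bit-identical to a sequential per-column sum;
        # motif column j of a minus hit reads the complement of forward
        # position L-1-j
        raw_f = np.zeros(idx.shape[0])
        raw_r = np.zeros(idx.shape[0])
        for j in range(L):
            raw_f += fwd[idx[:, j], j]
            raw_r += rev[idx[:, L - 1 - j], j]
        for strand, raw in (("+", raw_f), ("-", raw_r)):
            rel = (raw - p.score_min) / span if span > 0 else np.ones_like(raw)
            for s in np.nonzero(rel >= relative_threshold)[0]:
                hits.append(
                    MotifHit(
                        motif_id=p.motif_id,
                        tf_name=p.tf_name,
                        seq_id=seq.id,
                        start=int(s),
                        end=int(s) + L,
                        strand=strand,
                        raw_score=float(raw[s]),
                        relative_score=float(rel[s]),
                    )
                )
    hits.sort(key=MotifHit.sort_key)
    return hits


def read_fasta(path) -> list[DnaSequence]:
    """Load a (multi-record) FASTA file; lowercase bases are upcased."""
    records = [DnaSequence(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(path, seqs: list[DnaSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i : i + 70] + "\n")


def hits_to_rows(hits: list[MotifHit]) -> list[dict]:
    return [
        {
            "seq_id": h.seq_id,
            "motif_id": h.motif_id,
            "tf_name": h.tf_name,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "raw_score": h.raw_score,
            "relative_score": h.relative_score,
        }
        for h in hits
    ]
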