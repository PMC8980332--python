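import numpy as np
import pytest

from crmscan.motifs import DnaSequence, make_motif_profile, scan_sequence
from crmscan.simulate import build_mg_demo, make_profile


@pytest.fixture(scope="session")
def acgt_profile():
    """Length-4 identity matrix: consensus ACGT (a palindrome)."""
    return make_motif_profile("MA0001", "TFA", np.diag([10, 10, 10, 10]))


@pytest.fixture(scope="session")
def toy_profiles():
    """Two short, sharp synthetic motifs for scanning tests."""
    return [
        make_profile("TGACGTCA", sharpness=0.9, motif_id="T1", tf_name="Tf1"),
        make_profile("CCAAT", sharpness=0.8, motif_id="T2", tf_name="Tf2"),
    ]


@pytest.fixture(scope="session")
def mg_demo():
    """The full synthetic prescreen locus (seed 7), built once per session."""
    return build_mg_demo(seed=7)


def brute_force_scan(seq: DnaSequence, profiles, threshold):
    """Independent exhaustive double-strand window enumeration.

    Scores each window by a sequential per-column sum over the profile's
    PWM (reverse-strand windows are reverse-complemented first), entirely
    separate from the production scanning path.
    """
    from crmscan.motifs import BASE_INDEX, reverse_complement

    hits = []
    for p in profiles:
        L = p.pwm.shape[1]
        colmin = [min(p.pwm[i, j] for i in range(4)) for j in range(L)]
        for start in range(len(seq.bases) - L + 1):
            window = seq.bases[start : start + L]
            for strand in "+-":
                read = window if strand == "+" else reverse_complement(window)
                raw = 0.0
                for j, base in enumerate(read):
                    idx = BASE_INDEX.get(base)
                    raw += colmin[j] if idx is None else float(p.pwm[idx, j])
                rel = (raw - p.score_min) / (p.score_max - p.score_min)
                if rel >= threshold:
                    hits.append((start, start + L, strand, p.motif_id, raw, rel))
    hits.sort(key=lambda h: (h[0], h[3], h[2]))
    return hits


def hits_as_tuples(hits):
    return [
        (h.start, h.end, h.strand, h.motif_id, h.raw_score, h.relative_score)
        for h in hits
    ]


@pytest.fixture(scope="session")
def scan_oracle():
    return brute_force_scan
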