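import pytest

from mirsite import scan_all, scenario_gastric_like
from mirsite.duplex import count_hbonds

#: bond total of a window vs miRNA, written as the dumbest possible loop so
#: it can stand as an independent oracle for the vectorised scanner
def naive_bond_total(mirna_seq: str, window: str) -> int:
    total = 0
    L = len(mirna_seq)
    for i in range(L):
        total += count_hbonds(window[i], mirna_seq[L - 1 - i])
    return total


def naive_scan_starts(mirna_seq: str, transcript_seq: str, threshold_pct: float):
    """Brute-force scan: score every window, filter by bonds ratio."""
    from mirsite.duplex import max_bond_total

    L = len(mirna_seq)
    max_total = max_bond_total(mirna_seq)
    starts = []
    for s0 in range(len(transcript_seq) - L + 1):
        total = naive_bond_total(mirna_seq, transcript_seq[s0 : s0 + L])
        if 100.0 * total / max_total >= threshold_pct:
            starts.append(s0 + 1)
    return starts


@pytest.fixture(scope="session")
def truth():
    return scenario_gastric_like(seed=7)


@pytest.fixture(scope="session")
def scenario_sites(truth):
    return scan_all(truth.mirnas, truth.transcripts)
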