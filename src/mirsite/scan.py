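"""Sliding-window binding-site scan with ratio thresholding.

Every window of miRNA length along a transcript is scored as a gapless
antiparallel duplex; windows whose dG/dGm ratio meets the threshold
(default 90%, inclusive) become binding sites.  Every passing start is
kept — runs of adjacent overlapping starts are a real feature of the
tables this reproduces and are only collapsed at the reporting layer
(:func:`collapse_ranges`).

Coordinates are 1-based inclusive from the first nucleotide of the
5'UTR.  A site's region (5UTR / CDS / 3UTR) is assigned by its start
position, which keeps region labels deterministic for sites straddling
a boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .duplex import (
    DEFAULT_MODEL,
    BOND_MATRIX,
    DuplexScheme,
    EnergyModel,
    duplex,
    encode,
    max_bond_total,
)
from .sequence_io import MiRNASeq, Transcript

Region = Literal["5UTR", "CDS", "3UTR"]

DEFAULT_THRESHOLD_PCT = 90.0


@dataclass(frozen=True)
class BindingSite:
    """One predicted miRNA binding site on a transcript."""

    mirna_id: str
    gene: str
    start: int  # 1-based from the 5'UTR first nucleotide
    length: int
    dG: float
    dGm: float
    ratio_pct: float
    region: Region

    @property
    def end(self) -> int:
        """Last covered position, 1-based inclusive."""
        return self.start + self.length - 1

    def scheme(self, mirna: MiRNASeq, transcript: Transcript,
               model: EnergyModel = DEFAULT_MODEL) -> DuplexScheme:
        """Recompute the full pairing scheme for rendering."""
        window = transcript.seq[self.start - 1 : self.start - 1 + self.length]
        return duplex(mirna.seq, window, model)


@dataclass(frozen=True)
class SiteRange:
    """A run of same-miRNA starts collapsed for table display."""

    start_min: int
    start_max: int
    count: int
    dG_min: float  # most negative
    dG_max: float  # least negative

    def __post_init__(self) -> None:
        if self.start_min > self.start_max:
            raise ValueError("start_min > start_max")
        if self.count < 1:
            raise ValueError("count < 1")


def classify_region(start: int, transcript: Transcript) -> Region:
    """Region of a site by its start: 5UTR, then CDS, then 3UTR."""
    if start <= transcript.utr5_len:
        return "5UTR"
    if start <= transcript.utr5_len + transcript.cds_len:
        return "CDS"
    return "3UTR"


def _window_bond_totals(t_codes: np.ndarray, m_codes: np.ndarray) -> np.ndarray:
    """Bond totals of every window: result[s] scores the duplex at 0-based s.

    Antiparallel pairing means window position i opposes the miRNA base
    at index L-1-i, i.e. the reversed miRNA read along the window.
    """
    L = len(m_codes)
    n_windows = len(t_codes) - L + 1
    totals = np.zeros(n_windows, dtype=np.int64)
    m_rev = m_codes[::-1]
    for i in range(L):
        totals += BOND_MATRIX[t_codes[i : i + n_windows], m_rev[i]]
    return totals


def _window_paired_counts(t_codes: np.ndarray, m_codes: np.ndarray) -> np.ndarray:
    L = len(m_codes)
    n_windows = len(t_codes) - L + 1
    counts = np.zeros(n_windows, dtype=np.int64)
    m_rev = m_codes[::-1]
    for i in range(L):
        counts += BOND_MATRIX[t_codes[i : i + n_windows], m_rev[i]] > 0
    return counts


def scan(
    mirna: MiRNASeq,
    transcript: Transcript,
    model: EnergyModel = DEFAULT_MODEL,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> list[BindingSite]:
    """All windows of the transcript whose ratio meets the threshold.

    The comparison is ``>=``: a ratio of exactly the threshold is kept.
    Sites are returned sorted by start.  A transcript shorter than the
    miRNA yields an empty list with a warning.
    """
    L = mirna.length
    if transcript.length < L:
        warnings.warn(
            f"transcript {transcript.gene!r} shorter than miRNA "
            f"{mirna.id!r}; no windows to scan",
            stacklevel=2,
        )
        return []
    t_codes = encode(transcript.seq)
    m_codes = encode(mirna.seq)
    totals = _window_bond_totals(t_codes, m_codes)
    max_total = max_bond_total(mirna.seq)
    if model.ratio_mode == "paired":
        ratios = 100.0 * _window_paired_counts(t_codes, m_codes) / L
    else:
        ratios = 100.0 * totals / max_total
    d_gm = -model.k_e * max_total
    passing = np.flatnonzero(ratios >= threshold_pct)
    sites = []
    for s0 in passing:
        start = int(s0) + 1
        sites.append(
            BindingSite(
                mirna_id=mirna.id,
                gene=transcript.gene,
                start=start,
                length=L,
                dG=-model.k_e * float(totals[s0]),
                dGm=d_gm,
                ratio_pct=float(ratios[s0]),
                region=classify_region(start, transcript),
            )
        )
    return sites


def scan_all(
    mirnas: Sequence[MiRNASeq],
    transcripts: Sequence[Transcript],
    model: EnergyModel = DEFAULT_MODEL,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> list[BindingSite]:
    """Scan every miRNA against every transcript."""
    out: list[BindingSite] = []
    for t in transcripts:
        for m in mirnas:
            if t.length >= m.length:
                out.extend(scan(m, t, model, threshold_pct))
    return out


def collapse_ranges(
    sites: Sequence[BindingSite], max_gap: Optional[int] = None
) -> list[SiteRange]:
    """Collapse runs of nearby same-miRNA starts into SiteRanges.

    Successive starts differing by at most ``max_gap`` join one run;
    the default gap is ``length - 1`` (i.e. the sites overlap).  All
    sites must share one miRNA and one gene.
    """
    if not sites:
        return []
    ids = {s.mirna_id for s in sites}
    genes = {s.gene for s in sites}
    if len(ids) > 1 or len(genes) > 1:
        raise ValueError(
            f"collapse_ranges expects one miRNA/gene, got {ids} / {genes}"
        )
    ordered = sorted(sites, key=lambda s: s.start)
    gap = max_gap if max_gap is not None else ordered[0].length - 1
    runs: list[list[BindingSite]] = [[ordered[0]]]
    for s in ordered[1:]:
        if s.start - runs[-1][-1].start <= gap:
            runs[-1].append(s)
        else:
            runs.append([s])
    return [
        SiteRange(
            start_min=r[0].start,
            start_max=r[-1].start,
            count=len(r),
            dG_min=min(s.dG for s in r),
            dG_max=max(s.dG for s in r),
        )
        for r in runs
    ]


def format_range(r: SiteRange, glyph: str = "÷") -> str:
    """Format a collapsed run the way the site tables print them.

    One start prints bare ("85"); two print comma-separated
    ("2288, 2290"); three or more print "first {glyph} last (count)"
    e.g. "4042 ÷ 4062 (11)".  ``glyph="-"`` gives an ASCII fallback.
    """
    if r.count == 1:
        return str(r.start_min)
    if r.count == 2:
        return f"{r.start_min}, {r.start_max}"
    return f"{r.start_min} {glyph} {r.start_max} ({r.count})"


def format_energy_range(r: SiteRange, glyph: str = "÷") -> str:
    """Format the dG column of a collapsed run, least-negative first."""
    lo, hi = round(r.dG_min), round(r.dG_max)
    if lo == hi:
        return str(hi)
    if r.count == 2:
        return f"{hi}, {lo}"
    return f"{hi} {glyph} {lo}"
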