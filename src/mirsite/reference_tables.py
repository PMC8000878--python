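"""Published MirTarget site tables for gastric-cancer candidate genes.

These are the printed per-site characteristics (start, length, dG) of
the binding-site clusters reported for a panel of gastric-cancer
candidate genes, transcribed row by row.  They serve two purposes:

* worked-example inputs — feeding a gene's rows into
  :func:`mirsite.clusters.find_clusters` must reproduce the published
  summed site lengths, spans and compaction ratios;
* an audit — :func:`audit_cluster_claims` recomputes each cluster's
  span/sum/compaction from its own rows and flags published summary
  figures that cannot be derived from them (the ODC1 and MAPK1
  compaction figures are known not to be).

Rows with three or more starts are printed only as "first ÷ last (n)";
the intermediate starts are not recoverable, so those rows carry
(start_min, start_max, count) and such genes cannot be expanded into
individual BindingSite intervals — the audit works from counts alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .scan import BindingSite, Region


@dataclass(frozen=True)
class TableRow:
    """One printed table row: a miRNA's starts on one gene/region."""

    mirna: str
    start_min: int
    start_max: int
    count: int
    length: int
    dG: float  # representative printed value (first of the row)

    @property
    def sum_len(self) -> int:
        return self.count * self.length

    @property
    def max_end(self) -> int:
        return self.start_max + self.length - 1

    @property
    def explicit_starts(self) -> tuple[int, ...]:
        """Individual starts, available only when all were printed."""
        if self.count == 1:
            return (self.start_min,)
        if self.count == 2:
            return (self.start_min, self.start_max)
        raise ValueError(
            f"{self.mirna}: run of {self.count} starts printed only as "
            "endpoints; individual starts unrecoverable"
        )


@dataclass(frozen=True)
class ClusterClaim:
    """Published summary figures for one binding-site cluster."""

    gene: str
    region: Region
    rows: tuple[TableRow, ...]
    claimed_span_len: Optional[int] = None
    claimed_sum_len: Optional[int] = None
    claimed_compaction: Optional[float] = None

    @property
    def derived_sum_len(self) -> int:
        return sum(r.sum_len for r in self.rows)

    @property
    def derived_span_len(self) -> int:
        start = min(r.start_min for r in self.rows)
        end = max(r.max_end for r in self.rows)
        return end - start + 1

    @property
    def derived_compaction(self) -> float:
        return self.derived_sum_len / self.derived_span_len

    def to_sites(self) -> list[BindingSite]:
        """Expand rows into one BindingSite per printed start."""
        sites = []
        for r in self.rows:
            for start in r.explicit_starts:
                sites.append(
                    BindingSite(
                        mirna_id=r.mirna,
                        gene=self.gene,
                        start=start,
                        length=r.length,
                        dG=r.dG,
                        dGm=r.dG,  # not printed; placeholder
                        ratio_pct=100.0,
                        region=self.region,
                    )
                )
        return sites


def _r(mirna, start, length, dG, start2=None, count=None):
    if count is None:
        count = 1 if start2 is None else 2
    return TableRow(
        mirna=mirna,
        start_min=start,
        start_max=start2 if start2 is not None else start,
        count=count,
        length=length,
        dG=dG,
    )


ARID1A_5UTR = ClusterClaim(
    gene="ARID1A",
    region="5UTR",
    rows=(
        _r("ID02106.3p-miR", 136, 23, -123),
        _r("ID01778.3p-miR", 140, 24, -134),
        _r("ID00296.3p-miR", 141, 25, -138, start2=166),
        _r("miR-6081", 143, 24, -125),
        _r("ID01702.3p-miR", 147, 24, -134),
        _r("ID00465.5p-miR", 148, 20, -113),
        _r("ID01377.3p-miR", 152, 20, -117),
        _r("ID02592.5p-miR", 164, 23, -123, start2=167),
        _r("miR-3960", 167, 20, -115),
        _r("ID03065.3p-miR", 172, 21, -115),
    ),
    claimed_span_len=57,
    claimed_sum_len=272,
    claimed_compaction=4.8,
)

E2F1_5UTR = ClusterClaim(
    gene="E2F1",
    region="5UTR",
    rows=(
        _r("ID02574.3p-miR", 84, 20, -115),
        _r("ID02052.5p-miR", 85, 24, -149),
        _r("ID01873.3p-miR", 87, 21, -123),
        _r("miR-3960", 90, 20, -115),
        _r("ID00071.3p-miR", 90, 20, -117),
        _r("ID00722.5p-miR", 90, 20, -113),
        _r("ID02064.5p-miR", 95, 23, -132),
    ),
    claimed_span_len=35,
    claimed_sum_len=148,
    claimed_compaction=4.2,
)

ODC1_5UTR = ClusterClaim(
    gene="ODC1",
    region="5UTR",
    rows=(
        _r("ID00756.3p-miR", 9, 23, -129),
        _r("ID01804.3p-miR", 13, 23, -132),
        _r("ID02187.5p-miR", 14, 23, -123),
        _r("ID00457.3p-miR", 15, 22, -123, start2=21),
        _r("ID02084.3p-miR", 17, 24, -140),
        _r("ID02064.5p-miR", 17, 23, -129, start2=23, count=3),
        _r("miR-3960", 18, 20, -115, start2=21, count=3),
        _r("ID01652.3p-miR", 19, 23, -125),
        _r("ID02538.3p-miR", 19, 22, -123),
        _r("ID01702.3p-miR", 19, 24, -134, start2=22),
        _r("ID02229.3p-miR", 21, 21, -121),
        _r("ID02499.3p-miR", 21, 21, -119),
        _r("ID01157.5p-miR", 22, 20, -117),
        _r("ID01377.3p-miR", 23, 20, -121),
        _r("ID00061.3p-miR", 24, 22, -125),
    ),
    claimed_span_len=38,
    claimed_compaction=10.6,
)

PIK3CA_5UTR = ClusterClaim(
    gene="PIK3CA",
    region="5UTR",
    rows=(
        _r("ID00296.3p-miR", 1, 25, -134),
        _r("ID01190.5p-miR", 4, 24, -140),
        _r("ID01702.3p-miR", 4, 24, -140),
        _r("ID01895.5p-miR", 4, 24, -132),
        _r("ID01641.3p-miR", 5, 24, -127),
        _r("ID00966.5p-miR", 6, 24, -136),
        _r("ID00030.3p-miR", 7, 22, -121),
        _r("ID02294.5p-miR", 7, 24, -125),
        _r("ID01804.3p-miR", 8, 23, -134),
        _r("ID01873.3p-miR", 8, 21, -123),
        _r("ID02064.5p-miR", 9, 23, -127),
        _r("ID02084.3p-miR", 9, 24, -129),
    ),
    claimed_span_len=33,
    claimed_sum_len=282,
    claimed_compaction=8.5,
)

TBC1D9_5UTR = ClusterClaim(
    gene="TBC1D9",
    region="5UTR",
    rows=(
        _r("ID01895.5p-miR", 125, 24, -134),
        _r("ID02187.5p-miR", 130, 23, -127),
        _r("ID03229.5p-miR", 130, 22, -121, start2=133),
        _r("ID01041.5p-miR", 132, 24, -132),
        _r("ID01702.3p-miR", 136, 24, -140),
        _r("ID02084.3p-miR", 137, 24, -136),
        _r("ID00457.3p-miR", 138, 22, -125),
    ),
    claimed_span_len=37,
    claimed_compaction=5.0,
)

ARID1A_CDS = ClusterClaim(
    gene="ARID1A",
    region="CDS",
    rows=(
        _r("ID02052.5p-miR", 410, 24, -132),
        _r("ID00522.5p-miR", 410, 23, -127),
        _r("ID02187.5p-miR", 411, 23, -127),
        _r("ID02692.5p-miR", 413, 23, -127),
        _r("ID00457.3p-miR", 415, 22, -125),
        _r("ID02064.5p-miR", 417, 23, -134),
        _r("ID02084.3p-miR", 418, 24, -138),
        _r("ID02538.3p-miR", 420, 22, -125),
    ),
    claimed_span_len=32,
    claimed_sum_len=184,
    claimed_compaction=5.8,
)

MAPK1_CDS = ClusterClaim(
    gene="MAPK1",
    region="CDS",
    rows=(
        _r("ID03332.3p-miR", 243, 24, -134),
        _r("ID01310.3p-miR", 244, 22, -121),
        _r("ID00798.3p-miR", 246, 24, -136),
        _r("ID01546.5p-miR", 246, 24, -132),
    ),
    claimed_span_len=28,
    claimed_compaction=2.9,
)

VEGFC_CDS = ClusterClaim(
    gene="VEGFC",
    region="CDS",
    rows=(
        _r("ID02052.5p-miR", 498, 24, -132),
        _r("ID02187.5p-miR", 500, 23, -123),
        _r("ID01041.5p-miR", 501, 24, -132),
        _r("ID01873.3p-miR", 501, 21, -123),
        _r("ID00457.3p-miR", 503, 22, -127),
        _r("miR-3960", 504, 20, -115),
        _r("ID02064.5p-miR", 505, 23, -129),
    ),
    claimed_span_len=31,
    claimed_compaction=5.1,
)

ALL_CLAIMS: tuple[ClusterClaim, ...] = (
    ARID1A_5UTR,
    E2F1_5UTR,
    ODC1_5UTR,
    PIK3CA_5UTR,
    TBC1D9_5UTR,
    ARID1A_CDS,
    MAPK1_CDS,
    VEGFC_CDS,
)

#: printed spans drift by +/-1 nt against their own rows across tables
SPAN_TOLERANCE_NT = 1
#: compaction quoted to one decimal, derived from a +/-1 nt span
COMPACTION_TOLERANCE = 0.15


@dataclass(frozen=True)
class AuditResult:
    """Verdict of recomputing one cluster's summary from its rows."""

    gene: str
    region: Region
    derived_span_len: int
    derived_sum_len: int
    derived_compaction: float
    span_consistent: Optional[bool]
    sum_consistent: Optional[bool]
    compaction_consistent: Optional[bool]
    claimed_span_len: Optional[int]
    claimed_sum_len: Optional[int]
    claimed_compaction: Optional[float]

    @property
    def consistent(self) -> bool:
        return all(
            v is not False
            for v in (self.span_consistent, self.sum_consistent,
                      self.compaction_consistent)
        )


def audit_cluster_claims(
    claims: Sequence[ClusterClaim] = ALL_CLAIMS,
    span_tol: int = SPAN_TOLERANCE_NT,
    compaction_tol: float = COMPACTION_TOLERANCE,
) -> list[AuditResult]:
    """Recompute span/sum/compaction per cluster and compare to the claims.

    A claimed compaction counts as consistent if it lies within
    ``compaction_tol`` of sum/span for the derived span adjusted by at
    most ``span_tol`` nt (the printed spans themselves wobble by 1 nt).
    Figures with no claim audit as None.  No corrected value is
    guessed for inconsistent claims; the derived figures are reported
    as-is.
    """
    results = []
    for c in claims:
        span = c.derived_span_len
        total = c.derived_sum_len
        span_ok = (
            None if c.claimed_span_len is None
            else abs(c.claimed_span_len - span) <= span_tol
        )
        sum_ok = (
            None if c.claimed_sum_len is None
            else c.claimed_sum_len == total
        )
        if c.claimed_compaction is None:
            comp_ok = None
        else:
            candidates = [
                total / s
                for s in range(span - span_tol, span + span_tol + 1)
                if s >= 1
            ]
            comp_ok = any(
                abs(c.claimed_compaction - x) <= compaction_tol
                for x in candidates
            )
        results.append(
            AuditResult(
                gene=c.gene,
                region=c.region,
                derived_span_len=span,
                derived_sum_len=total,
                derived_compaction=total / span,
                span_consistent=span_ok,
                sum_consistent=sum_ok,
                compaction_consistent=comp_ok,
                claimed_span_len=c.claimed_span_len,
                claimed_sum_len=c.claimed_sum_len,
                claimed_compaction=c.claimed_compaction,
            )
        )
    return results
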