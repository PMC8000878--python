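"""Binding-site cluster detection and compaction statistics.

Sites (from any miRNAs) whose intervals overlap — directly or through
a chain of overlaps — form a cluster.  Clusters are the connected
components of the interval-overlap graph; intervals are 1-based
inclusive, and two intervals that merely touch end-to-start without
sharing a nucleotide do not connect.

A cluster's compaction ratio is the summed length of its member sites
divided by its span; values well above 1 mean many sites crowd one
short stretch of mRNA and must compete for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .scan import BindingSite, Region, SiteRange, collapse_ranges, format_energy_range, format_range
from .sequence_io import Transcript


@dataclass(frozen=True)
class SiteCluster:
    """A maximal set of transitively overlapping binding sites on one gene."""

    gene: str
    region: Region
    members: tuple[BindingSite, ...]
    span_start: int
    span_end: int

    @property
    def span_len(self) -> int:
        return self.span_end - self.span_start + 1

    @property
    def sum_len(self) -> int:
        """Summed member lengths; every reported start counts once."""
        return sum(m.length for m in self.members)

    @property
    def compaction(self) -> float:
        return self.sum_len / self.span_len

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.mirna_id for m in self.members}))


def find_clusters(sites: Sequence[BindingSite]) -> list[SiteCluster]:
    """Connected components of the interval-overlap graph of one gene's sites.

    Sorted-sweep construction: after ordering by start, a new cluster
    opens whenever a site starts beyond the furthest end seen so far —
    for intervals this is exactly the transitive-overlap partition.
    Clusters come back sorted by span start; each cluster's region is
    that of its span start (members may straddle region boundaries).
    """
    if not sites:
        return []
    genes = {s.gene for s in sites}
    if len(genes) > 1:
        raise ValueError(f"find_clusters expects sites of one gene, got {genes}")
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_id))
    groups: list[list[BindingSite]] = [[ordered[0]]]
    max_end = ordered[0].end
    for s in ordered[1:]:
        if s.start <= max_end:  # shares >= 1 nt with the running component
            groups[-1].append(s)
        else:
            groups.append([s])
            max_end = s.end
        max_end = max(max_end, s.end)
    clusters = []
    for g in groups:
        span_start = min(m.start for m in g)
        span_end = max(m.end for m in g)
        anchor = min(g, key=lambda m: m.start)
        clusters.append(
            SiteCluster(
                gene=g[0].gene,
                region=anchor.region,
                members=tuple(g),
                span_start=span_start,
                span_end=span_end,
            )
        )
    return clusters


def find_clusters_by_gene(sites: Sequence[BindingSite]) -> list[SiteCluster]:
    """Cluster a multi-gene site list gene by gene."""
    by_gene: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene, []).append(s)
    out: list[SiteCluster] = []
    for gene in sorted(by_gene):
        out.extend(find_clusters(by_gene[gene]))
    return out


def cluster_stats(c: SiteCluster) -> tuple[int, int, float]:
    """(span_len, sum_len, compaction) with compaction to one decimal."""
    return c.span_len, c.sum_len, round(c.compaction, 1)


def cluster_table(
    clusters: Sequence[SiteCluster],
    transcripts: Optional[Sequence[Transcript]] = None,
    glyph: str = "÷",
) -> pd.DataFrame:
    """Per-member table rows in the published layout.

    One row per (cluster, miRNA) with that miRNA's starts collapsed to
    a range string; gene/NX/region/span/compaction repeat on each row
    of the cluster.
    """
    nx = {t.gene: t.nx for t in transcripts or []}
    rows = []
    for ci, c in enumerate(clusters):
        by_mirna: dict[str, list[BindingSite]] = {}
        for m in c.members:
            by_mirna.setdefault(m.mirna_id, []).append(m)
        for mirna_id in sorted(by_mirna, key=lambda k: min(s.start for s in by_mirna[k])):
            member_sites = by_mirna[mirna_id]
            for r in collapse_ranges(member_sites):
                rows.append(
                    {
                        "gene": c.gene,
                        "nx": nx.get(c.gene),
                        "region": c.region,
                        "cluster": ci,
                        "span": f"{c.span_start} {glyph} {c.span_end}",
                        "span_len": c.span_len,
                        "sum_len": c.sum_len,
                        "compaction": round(c.compaction, 1),
                        "mirna": mirna_id,
                        "starts": format_range(r, glyph),
                        "dG_kJ_mole": format_energy_range(r, glyph),
                        "length": member_sites[0].length,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "nx", "region", "cluster", "span", "span_len", "sum_len",
            "compaction", "mirna", "starts", "dG_kJ_mole", "length",
        ],
    )
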