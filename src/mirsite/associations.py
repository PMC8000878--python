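"""miRNA-gene association tables, expression report and suppression model.

Associations are derived from threshold-filtered sites: a miRNA with
binding sites in two or more genes has "alternative target genes"; a
gene bound by two or more miRNAs has "alternative miRNAs".  Site
effectiveness uses region-specific free-energy cutoffs (stronger =
more negative): -130 kJ/mole for the 5'UTR and CDS, -115 kJ/mole for
the 3'UTR, where sites are typically AU-richer and weaker.

Translational suppression is modelled from the miRNA:mRNA
concentration ratio R with the occupancy form 100*R/(1+R): at R=1:10
roughly 10% of message is occupied, at R=10:1 roughly 90%, and
s(R) + s(1/R) = 100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .clusters import SiteCluster, find_clusters_by_gene
from .scan import BindingSite, Region
from .sequence_io import Transcript

DEFAULT_REGION_THRESHOLDS: dict[Region, float] = {
    "5UTR": -130.0,
    "CDS": -130.0,
    "3UTR": -115.0,
}


@dataclass(frozen=True)
class AssociationRecord:
    """One miRNA and its alternative target genes (n >= 2)."""

    mirna_id: str
    genes: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneAssociation:
    """One gene and its alternative miRNAs (n >= 2)."""

    gene: str
    mirnas: tuple[str, ...]

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)


def effective_sites(
    sites: Sequence[BindingSite],
    region_thresholds: Optional[Mapping[Region, float]] = None,
) -> list[BindingSite]:
    """Keep sites at least as strong as their region's energy cutoff.

    "-130 kJ/mole and higher (stronger)" means dG <= -130: free
    energies are negative, so a stronger site is more negative.
    """
    thresholds = dict(DEFAULT_REGION_THRESHOLDS)
    if region_thresholds:
        thresholds.update(region_thresholds)
    for region, thr in thresholds.items():
        if thr >= 0:
            raise ValueError(f"threshold for {region} must be negative, got {thr}")
    return [s for s in sites if s.dG <= thresholds[s.region]]


def alternatives(
    sites: Sequence[BindingSite],
) -> tuple[list[AssociationRecord], list[GeneAssociation]]:
    """Alternative-target and alternative-miRNA tables from filtered sites.

    Output is deterministically sorted: by descending gene count then
    miRNA id, and by descending miRNA count then gene.  Entries with a
    single partner are omitted.
    """
    genes_by_mirna: dict[str, set[str]] = {}
    mirnas_by_gene: dict[str, set[str]] = {}
    for s in sites:
        genes_by_mirna.setdefault(s.mirna_id, set()).add(s.gene)
        mirnas_by_gene.setdefault(s.gene, set()).add(s.mirna_id)
    recs = [
        AssociationRecord(mirna_id=m, genes=tuple(sorted(gs)))
        for m, gs in genes_by_mirna.items()
        if len(gs) >= 2
    ]
    recs.sort(key=lambda r: (-r.n_genes, r.mirna_id))
    gene_recs = [
        GeneAssociation(gene=g, mirnas=tuple(sorted(ms)))
        for g, ms in mirnas_by_gene.items()
        if len(ms) >= 2
    ]
    gene_recs.sort(key=lambda r: (-r.n_mirnas, r.gene))
    return recs, gene_recs


def suppression(mirna_conc: float, mrna_conc: float) -> float:
    """Percent suppression of protein synthesis from concentrations.

    Occupancy form 100*R/(1+R) with R = [miRNA]/[mRNA]; monotone in R,
    0 at R=0, saturating at 100.
    """
    if mirna_conc < 0:
        raise ValueError("miRNA concentration must be non-negative")
    if mrna_conc <= 0:
        raise ValueError("mRNA concentration must be positive")
    r = mirna_conc / mrna_conc
    return 100.0 * r / (1.0 + r)


def suppression_from_ratio(r: float) -> float:
    """Suppression percent directly from the concentration ratio R."""
    return suppression(r, 1.0)


def competition_rank(
    cluster: SiteCluster,
    expressions: Optional[Mapping[str, float]] = None,
) -> list[tuple[str, float]]:
    """Rank a cluster's miRNAs by competitive advantage.

    The two stated advantage factors — stronger binding (more negative
    dG) and higher concentration — are combined as the heuristic score
    ``rel_expression * |dG|`` (best dG per miRNA; missing expression
    counts as 1).  Descending score, ties broken by miRNA id.
    """
    expressions = expressions or {}
    best_dg: dict[str, float] = {}
    for m in cluster.members:
        if m.mirna_id not in best_dg or m.dG < best_dg[m.mirna_id]:
            best_dg[m.mirna_id] = m.dG
    scored = [
        (mid, expressions.get(mid, 1.0) * abs(dg))
        for mid, dg in best_dg.items()
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def nx_site_report(
    transcripts: Sequence[Transcript],
    sites: Sequence[BindingSite],
) -> pd.DataFrame:
    """Per-gene expression vs site-count table.

    Columns: gene, nx, n_sites, n_multi_clusters (clusters with >= 2
    members).  Sorted by NX descending with missing NX last — the
    pattern of interest being that highly expressed genes tend to
    carry only scattered single sites, not clusters.
    """
    by_gene: dict[str, list[BindingSite]] = {t.gene: [] for t in transcripts}
    for s in sites:
        by_gene.setdefault(s.gene, []).append(s)
    rows = []
    for t in transcripts:
        gsites = by_gene.get(t.gene, [])
        clusters = find_clusters_by_gene(gsites) if gsites else []
        rows.append(
            {
                "gene": t.gene,
                "nx": t.nx,
                "n_sites": len(gsites),
                "n_multi_clusters": sum(1 for c in clusters if c.n_members >= 2),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "nx", "n_sites", "n_multi_clusters"])
    return df.sort_values(
        by=["nx", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
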