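"""Synthetic miRNA/transcript cosmos with planted binding sites.

Real inputs for this kind of analysis (transcript accessions, thousands
of miRNAs) cannot be bundled, so every pipeline stage is exercised on
generated data instead.  The generator plants binding sites with
controlled position and duplex quality and emits a truth ledger, so
recovery, clustering and association behaviour can all be checked
against exactly known answers.

Two planting mechanisms are used:

* *write plants* overwrite a transcript window with the (optionally
  degraded) reverse complement of a miRNA.  Later plants overwrite
  earlier ones where they overlap — overlap is the object of study, so
  conflicts are resolved by overwrite-in-order and every plant's
  realized duplex quality is recomputed from the final sequence.
* *family variants* derive new miRNAs from an already-planted miRNA by
  substituting one or two bases.  Their sites coincide with the parent
  plant, which is how clusters of overlapping sites of *different*
  miRNAs arise without destroying each other — mirroring how miRNA
  family members (differing by 1-3 nt) share binding sites.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .duplex import DEFAULT_MODEL, EnergyModel, duplex, reverse_complement
from .scan import classify_region
from .sequence_io import (
    MiRNASeq,
    Transcript,
    write_mirna_fasta,
    write_regions_tsv,
    write_transcript_fasta,
)

_BASES = np.array(list("ACGU"))

#: replacement bases forming no scored pair with the opposing miRNA base
_NON_PAIRING = {"G": "AG", "A": "AG", "C": "CU", "U": "CU"}


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one miRNA site at a transcript position."""

    mirna_id: str
    start: int  # 1-based
    target_ratio_pct: float = 100.0  # paired-mode fraction to realize

    def __post_init__(self) -> None:
        if not 0 <= self.target_ratio_pct <= 100:
            raise ValueError("target_ratio_pct outside [0, 100]")


@dataclass(frozen=True)
class PlantRecord:
    """Truth-ledger entry: one planted site with realized duplex quality.

    Realized values are recomputed from the final transcript sequence,
    so they reflect any overwriting by later overlapping plants.
    """

    gene: str
    mirna_id: str
    start: int
    length: int
    target_ratio_pct: float
    realized_paired_pct: float
    realized_bonds_pct: float
    realized_dG: float
    region: str

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SyntheticTruth:
    """A generated cosmos: sequences plus the planted-site ledger."""

    transcripts: list[Transcript]
    mirnas: list[MiRNASeq]
    plants: list[PlantRecord]
    seed: int

    def mirna_by_id(self, mirna_id: str) -> MiRNASeq:
        for m in self.mirnas:
            if m.id == mirna_id:
                return m
        raise KeyError(mirna_id)

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA + regions TSV + truth TSV into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mirna_fasta(self.mirnas, outdir / "mirnas.fa")
        write_transcript_fasta(self.transcripts, outdir / "transcripts.fa")
        write_regions_tsv(self.transcripts, outdir / "regions.tsv")
        write_truth_tsv(self.plants, outdir / "truth.tsv")


def write_truth_tsv(plants: Sequence[PlantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["gene", "start", "end", "mirna", "target_ratio_pct",
             "realized_paired_pct", "realized_bonds_pct", "realized_dG", "region"]
        )
        for p in plants:
            w.writerow(
                [p.gene, p.start, p.end, p.mirna_id,
                 f"{p.target_ratio_pct:.1f}", f"{p.realized_paired_pct:.1f}",
                 f"{p.realized_bonds_pct:.1f}", f"{p.realized_dG:.1f}", p.region]
            )


def random_mirnas(
    n: int,
    length_range: tuple[int, int] = (20, 25),
    gc_frac: float = 0.5,
    seed: int = 0,
    prefix: str = "syn",
) -> list[MiRNASeq]:
    """Random miRNAs with per-base G/C probability ``gc_frac``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= gc_frac <= 1:
        raise ValueError("gc_frac outside [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        gc = rng.random(length) < gc_frac
        strong = rng.choice(list("GC"), size=length)
        weak = rng.choice(list("AU"), size=length)
        seq = "".join(np.where(gc, strong, weak))
        out.append(MiRNASeq(id=f"{prefix}-{i:03d}-miR", seq=seq))
    return out


def random_background(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _degraded_site(mirna: MiRNASeq, target_ratio_pct: float,
                   rng: np.random.Generator) -> str:
    """The miRNA's perfect site with k positions broken to hit the target.

    k = round(L * (1 - target/100)) window positions are substituted by
    bases forming no scored pair with the opposing miRNA base, sampled
    away from both duplex ends so the realized paired fraction is
    exactly (L - k) / L.
    """
    L = mirna.length
    site = list(reverse_complement(mirna.seq))
    k = round(L * (1.0 - target_ratio_pct / 100.0))
    if k == 0:
        return "".join(site)
    interior = list(range(2, L - 2))
    if k > len(interior):
        raise ValueError(f"target ratio {target_ratio_pct} unreachable for length {L}")
    positions = rng.choice(interior, size=k, replace=False)
    for pos in positions:
        partner = mirna.seq[L - 1 - pos]  # antiparallel opposing base
        site[pos] = rng.choice(list(_NON_PAIRING[partner]))
    return "".join(site)


def plant_sites(
    gene: str,
    transcript_len: int,
    regions: tuple[int, int, int],
    plants: Sequence[PlantSpec],
    mirnas: Sequence[MiRNASeq],
    seed: int = 0,
    nx: Optional[float] = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> tuple[Transcript, list[PlantRecord]]:
    """Build one transcript with the requested plants over random background.

    Plants are applied in order; overlapping plants overwrite earlier
    bases.  The returned ledger holds each plant's realized paired- and
    bonds-mode ratios recomputed from the final sequence.
    """
    utr5, cds, utr3 = regions
    if utr5 + cds + utr3 != transcript_len:
        raise ValueError("region lengths do not sum to transcript length")
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in mirnas}
    seq = list(random_background(transcript_len, rng))
    for p in plants:
        m = by_id[p.mirna_id]
        if p.start < 1 or p.start + m.length - 1 > transcript_len:
            raise ValueError(
                f"plant {p.mirna_id}@{p.start} outside transcript of "
                f"length {transcript_len}"
            )
        site = _degraded_site(m, p.target_ratio_pct, rng)
        seq[p.start - 1 : p.start - 1 + m.length] = site
    transcript = Transcript(
        gene=gene, seq="".join(seq), utr5_len=utr5, cds_len=cds,
        utr3_len=utr3, nx=nx,
    )
    records = [
        _realize(transcript, by_id[p.mirna_id], p.start,
                 p.target_ratio_pct, model)
        for p in plants
    ]
    return transcript, records


def _realize(
    transcript: Transcript,
    mirna: MiRNASeq,
    start: int,
    target_ratio_pct: float,
    model: EnergyModel = DEFAULT_MODEL,
) -> PlantRecord:
    """Score a planted window on the final sequence into a ledger record."""
    window = transcript.seq[start - 1 : start - 1 + mirna.length]
    sch = duplex(mirna.seq, window, model)
    return PlantRecord(
        gene=transcript.gene,
        mirna_id=mirna.id,
        start=start,
        length=mirna.length,
        target_ratio_pct=target_ratio_pct,
        realized_paired_pct=100.0 * sch.n_paired / sch.length,
        realized_bonds_pct=100.0 * sch.dG / sch.dGm,
        realized_dG=sch.dG,
        region=classify_region(start, transcript),
    )


def _family_variants(
    base: MiRNASeq, sub_counts: Sequence[int], rng: np.random.Generator
) -> list[MiRNASeq]:
    """Derive family members from a miRNA, one per entry of ``sub_counts``.

    A single substitution costs at most 3 hydrogen bonds against the
    parent's perfect site, so one-substitution variants always keep a
    bonds ratio above 93% there; two-substitution variants may dip
    below the 90% scan threshold, which is wanted for diversity.
    """
    out = []
    for i, n_subs in enumerate(sub_counts):
        seq = list(base.seq)
        positions = rng.choice(range(2, base.length - 2), size=n_subs, replace=False)
        for pos in positions:
            choices = [b for b in "ACGU" if b != seq[pos]]
            seq[pos] = rng.choice(choices)
        out.append(MiRNASeq(id=f"{base.id}-v{i + 1}", seq="".join(seq)))
    return out


def _gc_rich_mirna(
    mirna_id: str, length: int, min_gc: int, rng: np.random.Generator,
    rel_expression: Optional[float] = None,
) -> MiRNASeq:
    """A random miRNA with a guaranteed minimum G+C count.

    The floor keeps the miRNA's perfect and near-perfect sites above
    the strongest region energy cutoff regardless of sampling noise.
    """
    while True:
        gc = rng.random(length) < 0.65
        if gc.sum() >= min_gc:
            break
    strong = rng.choice(list("GC"), size=length)
    weak = rng.choice(list("AU"), size=length)
    seq = "".join(np.where(gc, strong, weak))
    return MiRNASeq(id=mirna_id, seq=seq, rel_expression=rel_expression)


# region layout shared by every scenario gene: 200 nt leader, 900 nt CDS,
# 400 nt trailer
_SCEN_REGIONS = (200, 900, 400)
_SCEN_LEN = sum(_SCEN_REGIONS)


def scenario_gastric_like(
    seed: int = 7, model: EnergyModel = DEFAULT_MODEL
) -> SyntheticTruth:
    """A small fixed cosmos emulating the shapes of the published tables.

    10 genes, ~40 miRNAs: a ten-plant tiling cluster in one 5'UTR, two
    miRNA-family clusters of coincident overlapping sites, GU- and
    CA-dinucleotide-repeat sites, a hub miRNA with six target genes
    (giving the alternatives table a six-gene row and one gene six
    alternative miRNAs), isolated singletons on highly expressed genes,
    and two below-threshold plants for negative recovery checks.
    """
    rng = np.random.default_rng(seed)

    background_mirnas = random_mirnas(
        20, (20, 25), gc_frac=0.55, seed=int(rng.integers(2**31)), prefix="syn-r"
    )
    # family bases and the hub carry a GC floor so their (near-)perfect
    # sites clear the -130/-115 kJ/mole effectiveness cutoffs
    fam_a_base = _gc_rich_mirna("syn-famA-miR", 23, min_gc=13, rng=rng)
    fam_b_base = _gc_rich_mirna("syn-famB-miR", 24, min_gc=13, rng=rng)
    fam_a = [fam_a_base] + _family_variants(fam_a_base, (1, 1, 1, 1, 1, 2, 2), rng)
    fam_b = [fam_b_base] + _family_variants(fam_b_base, (1, 1, 1, 2, 2), rng)
    hub = _gc_rich_mirna("syn-hub-miR", 23, min_gc=14, rng=rng,
                         rel_expression=4.8)
    # repeat miRNAs: sites are GU- / CA-dinucleotide repeats in the mRNA
    ca_rep = MiRNASeq(id="syn-carep-miR", seq="CA" * 11 + "C")  # site GUGU...
    gu_rep = MiRNASeq(id="syn-gurep-miR", seq="GU" * 11 + "G")  # site CACA...
    decoys = random_mirnas(
        2, (22, 24), gc_frac=0.55, seed=int(rng.integers(2**31)), prefix="syn-d"
    )
    mirnas = background_mirnas + fam_a + fam_b + [hub, ca_rep, gu_rep] + decoys

    transcripts: list[Transcript] = []
    plants: list[PlantRecord] = []

    def build(gene, nx, specs, family_plants=()):
        """One gene: write plants, then coincident family-variant records."""
        t, recs = plant_sites(
            gene, _SCEN_LEN, _SCEN_REGIONS, specs, mirnas,
            seed=int(rng.integers(2**31)), nx=nx, model=model,
        )
        for variant, start in family_plants:
            recs.append(_realize(t, variant, start, 100.0, model))
        transcripts.append(t)
        plants.extend(recs)

    # G01: ten-plant tiling cluster in the 5'UTR (overwrites cascade) and
    # an eight-member family cluster of coincident sites in the 3'UTR.
    tiling = [
        PlantSpec(background_mirnas[i].id, start)
        for i, start in enumerate((100, 104, 105, 107, 111, 112, 116, 128, 131, 136))
    ]
    fam_a_start = 1150
    build(
        "G01", 19.5,
        tiling + [PlantSpec(fam_a_base.id, fam_a_start)],
        family_plants=[(v, fam_a_start) for v in fam_a[1:]],
    )
    # G02: six-member family cluster in the 5'UTR, hub site in the 3'UTR
    fam_b_start = 120
    build(
        "G02", 3.4,
        [PlantSpec(fam_b_base.id, fam_b_start), PlantSpec(hub.id, 1200)],
        family_plants=[(v, fam_b_start) for v in fam_b[1:]],
    )
    # G03/G04: dinucleotide-repeat clusters plus hub sites
    build("G03", 19.2, [PlantSpec(ca_rep.id, 1250), PlantSpec(hub.id, 1350)])
    build("G04", 10.6, [PlantSpec(gu_rep.id, 1160), PlantSpec(hub.id, 100)])
    # G05/G06: hub sites plus below-threshold decoy plants
    build("G05", 10.0, [PlantSpec(hub.id, 1180),
                        PlantSpec(decoys[0].id, 500, target_ratio_pct=80.0)])
    build("G06", 8.9, [PlantSpec(hub.id, 400),
                       PlantSpec(decoys[1].id, 1250, target_ratio_pct=80.0),
                       PlantSpec(background_mirnas[10].id, 1400)])
    # G07: hub plus a mid-quality singleton
    build("G07", 4.6, [PlantSpec(hub.id, 1220),
                       PlantSpec(background_mirnas[11].id, 600,
                                 target_ratio_pct=92.0)])
    # G08-G10: highly expressed genes carrying one isolated site each
    build("G08", 76.6, [PlantSpec(background_mirnas[12].id, 1300)])
    build("G09", 963.7, [PlantSpec(background_mirnas[13].id, 1250)])
    build("G10", 25.2, [PlantSpec(background_mirnas[14].id, 450)])

    return SyntheticTruth(
        transcripts=transcripts, mirnas=mirnas, plants=plants, seed=seed
    )
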