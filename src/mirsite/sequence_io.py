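"""Readers/writers and the canonical sequence/region data model.

Sequences are normalized to uppercase RNA (T->U) on input, so DNA FASTA
from public databases is accepted directly.  Transcript coordinates are
1-based inclusive, counted from the first nucleotide of the 5'UTR; BED
output converts to 0-based half-open.

Region annotation travels as a sidecar TSV (``gene / utr5_len / cds_len
/ utr3_len / nx``) rather than GFF: only three segment lengths per
transcript are needed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

from .duplex import RNA_ALPHABET

if TYPE_CHECKING:  # pragma: no cover
    from .scan import BindingSite

#: column order of the sites table
SITES_COLUMNS = ("gene", "nx", "mirna", "start", "dG_kJ_mole", "ratio_pct", "length")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA thymine to uracil."""
    return seq.upper().replace("T", "U")


def _validate_rna(seq: str, label: str) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"record {label!r}: non-ACGTU character {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class MiRNASeq:
    """A miRNA: identifier plus 5'->3' RNA sequence.

    ``rel_expression`` is an optional relative concentration (arbitrary
    units) used by the cluster-competition ranking.
    """

    id: str
    seq: str
    family: Optional[str] = None
    rel_expression: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        _validate_rna(self.seq, self.id)
        if self.rel_expression is not None and self.rel_expression < 0:
            raise ValueError(f"miRNA {self.id!r}: negative rel_expression")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """An mRNA with 5'UTR/CDS/3'UTR segment lengths and optional NX.

    NX is the consensus normalized expression of the gene across
    tissues.  ``cds_len`` need not be a multiple of three (annotations
    may be partial); ``partial_cds`` records that condition.
    """

    gene: str
    seq: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    nx: Optional[float] = None
    partial_cds: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        _validate_rna(self.seq, self.gene)
        for name in ("utr5_len", "cds_len", "utr3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene}: negative {name}")
        total = self.utr5_len + self.cds_len + self.utr3_len
        if total != len(self.seq):
            raise ValueError(
                f"{self.gene}: region lengths sum to {total} != "
                f"{len(self.seq)} (sequence length)"
            )
        object.__setattr__(
            self, "partial_cds", self.cds_len > 0 and self.cds_len % 3 != 0
        )

    @property
    def length(self) -> int:
        return len(self.seq)


def read_mirna_fasta(path: str | Path) -> list[MiRNASeq]:
    """Read miRNAs from FASTA, normalizing to uppercase RNA.

    Raises on duplicate identifiers or non-ACGTU characters (after
    T->U conversion).  Input order is preserved.
    """
    out: list[MiRNASeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate miRNA id {rec.id!r}")
        seen.add(rec.id)
        out.append(MiRNASeq(id=rec.id, seq=normalize_rna(str(rec.seq))))
    return out


def _parse_optional_float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None


def read_regions_tsv(path: str | Path) -> dict[str, dict]:
    """Read the region-annotation sidecar TSV keyed by gene."""
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "utr5_len", "cds_len", "utr3_len"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"regions TSV must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            gene = row["gene"].strip()
            rows[gene] = {
                "utr5_len": int(row["utr5_len"]),
                "cds_len": int(row["cds_len"]),
                "utr3_len": int(row["utr3_len"]),
                "nx": _parse_optional_float(row.get("nx") or ""),
            }
    return rows


def read_transcripts(fasta: str | Path, regions: str | Path) -> list[Transcript]:
    """Read transcript FASTA plus its regions TSV into Transcript objects.

    Every FASTA record must have a regions row, and the three segment
    lengths must sum to the sequence length.
    """
    region_rows = read_regions_tsv(regions)
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        gene = rec.id
        if gene not in region_rows:
            raise ValueError(f"no regions row for gene {gene!r}")
        r = region_rows[gene]
        t = Transcript(
            gene=gene,
            seq=normalize_rna(str(rec.seq)),
            utr5_len=r["utr5_len"],
            cds_len=r["cds_len"],
            utr3_len=r["utr3_len"],
            nx=r["nx"],
        )
        if t.partial_cds:
            warnings.warn(
                f"{gene}: CDS length {t.cds_len} not divisible by 3 "
                "(partial annotation?)",
                stacklevel=2,
            )
        out.append(t)
    return out


def write_mirna_fasta(mirnas: Iterable[MiRNASeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.id}\n{m.seq}\n")


def write_transcript_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene}\n{t.seq}\n")


def write_regions_tsv(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "utr5_len", "cds_len", "utr3_len", "nx"])
        for t in transcripts:
            w.writerow(
                [t.gene, t.utr5_len, t.cds_len, t.utr3_len,
                 "" if t.nx is None else t.nx]
            )


def write_sites_tsv(
    sites: Iterable["BindingSite"],
    path: str | Path,
    nx_by_gene: Optional[dict[str, Optional[float]]] = None,
) -> None:
    """Write one row per binding site in the standard table column order.

    dG is rounded to the nearest integer kJ/mole and the ratio to the
    nearest integer percent; starts and lengths are exact.
    """
    nx_by_gene = nx_by_gene or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SITES_COLUMNS)
        for s in sites:
            nx = nx_by_gene.get(s.gene)
            w.writerow(
                [
                    s.gene,
                    "" if nx is None else nx,
                    s.mirna_id,
                    s.start,
                    round(s.dG),
                    round(s.ratio_pct),
                    s.length,
                ]
            )


def read_sites_tsv(path: str | Path) -> list[dict]:
    """Re-parse a sites TSV into plain dict rows (round-trip checking)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                {
                    "gene": row["gene"],
                    "nx": _parse_optional_float(row["nx"]),
                    "mirna": row["mirna"],
                    "start": int(row["start"]),
                    "dG_kJ_mole": int(row["dG_kJ_mole"]),
                    "ratio_pct": int(row["ratio_pct"]),
                    "length": int(row["length"]),
                }
            )
    return out


def write_sites_bed(sites: Iterable["BindingSite"], path: str | Path) -> None:
    """Write sites as BED6: chrom=gene, 0-based half-open interval,
    name=miRNA id, score=round(ratio*10), strand '+'."""
    with open(path, "w") as fh:
        for s in sites:
            bed_start = s.start - 1
            bed_end = bed_start + s.length
            fh.write(
                f"{s.gene}\t{bed_start}\t{bed_end}\t{s.mirna_id}"
                f"\t{round(s.ratio_pct * 10)}\t+\n"
            )
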