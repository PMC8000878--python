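"""Cross-species comparison of binding-site cluster regions.

Orthologous cluster regions (with flanking sequence) are compared
column by column on a supplied alignment: flank identity, per-column
substitution classification (transition / transversion / indel), and
— when a miRNA duplex is given — the signed free-energy change each
substitution causes.  A substitution is "wobble-preserving" when the
replacement base still forms one of the scored pairs with the opposing
miRNA base (e.g. C->U opposite G trades G-C for the non-canonical G-U
and costs two hydrogen bonds rather than abolishing the step).

Alignment itself is out of scope: entries must be pre-aligned (equal
lengths, '-' for gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import SeqIO

from .duplex import DEFAULT_MODEL, EnergyModel, count_hbonds
from .sequence_io import MiRNASeq, normalize_rna

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


@dataclass(frozen=True)
class OrthologSet:
    """Aligned cluster regions (plus flanks) across species."""

    label: str
    entries: dict[str, str]  # species tag -> aligned RNA (with '-')
    flank5_len: int
    flank3_len: int

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("need at least two species")
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.label}: entries not aligned (lengths {sorted(lengths)})"
            )
        aln_len = lengths.pop()
        if self.flank5_len + self.flank3_len > aln_len:
            raise ValueError(f"{self.label}: flanks exceed alignment length")


@dataclass(frozen=True)
class SubstitutionRecord:
    """One differing alignment column between a reference and an alternate."""

    position: int  # 1-based within the compared strings
    ref_base: str
    alt_base: str
    klass: str  # transition | transversion | indel
    wobble_preserving: Optional[bool]  # None when no miRNA context given
    ddG: Optional[float]  # alt minus ref duplex energy, kJ/mole


def read_ortholog_fasta(
    path, label: str, flank5_len: int, flank3_len: int
) -> OrthologSet:
    """Load a pre-aligned multi-FASTA of ortholog regions (ids = species tags)."""
    entries = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        entries[rec.id] = normalize_rna(str(rec.seq))
    return OrthologSet(
        label=label, entries=entries, flank5_len=flank5_len, flank3_len=flank3_len
    )


def _column_identity(columns: list[tuple[str, ...]]) -> float:
    if not columns:
        return 100.0
    same = sum(1 for col in columns if len(set(col)) == 1)
    return 100.0 * same / len(columns)


def flank_identity(oset: OrthologSet) -> tuple[float, float, bool, bool]:
    """(pct5, pct3, all_identical5, all_identical3) over the flank windows.

    Identity is column-wise: a flank column counts as identical only
    when every species carries the same symbol.
    """
    seqs = list(oset.entries.values())
    n = len(seqs[0])
    cols5 = [tuple(s[i] for s in seqs) for i in range(oset.flank5_len)]
    cols3 = [tuple(s[i] for s in seqs) for i in range(n - oset.flank3_len, n)]
    pct5 = _column_identity(cols5)
    pct3 = _column_identity(cols3)
    return pct5, pct3, pct5 == 100.0, pct3 == 100.0


def classify_substitution(ref: str, alt: str) -> str:
    if ref == "-" or alt == "-":
        return "indel"
    if (ref in _PURINES and alt in _PURINES) or (
        ref in _PYRIMIDINES and alt in _PYRIMIDINES
    ):
        return "transition"
    return "transversion"


def substitutions(
    ref: str,
    alt: str,
    mirna: Optional[MiRNASeq] = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[SubstitutionRecord]:
    """Per-column differences between two aligned region strings.

    When a miRNA is supplied, ``ref``/``alt`` must be exactly the
    duplex window (miRNA length); column i then opposes the miRNA base
    at position length-i (antiparallel), giving ddG = k_e *
    (bonds_ref - bonds_alt) — positive values weaken the duplex.
    """
    if len(ref) != len(alt):
        raise ValueError(f"length mismatch {len(ref)} != {len(alt)} (no gaps?)")
    if mirna is not None and len(ref) != mirna.length:
        raise ValueError(
            f"region length {len(ref)} != miRNA length {mirna.length}"
        )
    out = []
    for i, (rb, ab) in enumerate(zip(ref, alt)):
        if rb == ab:
            continue
        klass = classify_substitution(rb, ab)
        wobble = None
        ddg = None
        if mirna is not None and klass != "indel":
            partner = mirna.seq[mirna.length - 1 - i]
            bonds_ref = count_hbonds(rb, partner)
            bonds_alt = count_hbonds(ab, partner)
            wobble = bonds_alt > 0
            ddg = model.k_e * (bonds_ref - bonds_alt)
        out.append(
            SubstitutionRecord(
                position=i + 1,
                ref_base=rb,
                alt_base=ab,
                klass=klass,
                wobble_preserving=wobble,
                ddG=ddg,
            )
        )
    return out


def insert_report(oset: OrthologSet) -> list[tuple[str, int, str]]:
    """Species-specific inserts: runs of columns where one species has
    bases and every other species has a gap.

    Returns (species, 1-based start column, inserted string) per run.
    """
    species = sorted(oset.entries)
    seqs = oset.entries
    n = len(next(iter(seqs.values())))
    out = []
    for sp in species:
        run_start = None
        run = []
        for i in range(n + 1):
            is_insert = (
                i < n
                and seqs[sp][i] != "-"
                and all(seqs[o][i] == "-" for o in species if o != sp)
            )
            if is_insert:
                if run_start is None:
                    run_start = i
                run.append(seqs[sp][i])
            elif run_start is not None:
                out.append((sp, run_start + 1, "".join(run)))
                run_start = None
                run = []
    out.sort(key=lambda t: (t[1], t[0]))
    return out
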