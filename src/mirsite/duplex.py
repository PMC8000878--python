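"""Gapless antiparallel miRNA:mRNA duplex scoring.

A duplex is scored by counting hydrogen bonds per opposing base pair:
3 for G-C, 2 for A-U, and 1 for each of the non-canonical (wobble-like)
pairs G-U and A-C; every other combination contributes nothing and is
treated as unpaired.  The hybridization free energy is a linear function
of the bond total, ``dG = -k_e * total_hbonds`` with a configurable
energy scale ``k_e`` (kJ/mole per hydrogen bond).  Each duplex is
normalized by ``dGm``, the energy of the miRNA bound to its exact
complement, giving the scale-free ratio ``100 * dG / dGm`` used for
site filtering.

The geometry is deliberately simple: full miRNA length, no gaps, no
bulges, antiparallel orientation (mRNA 5'->3' against miRNA 3'->5').
Nearest-neighbour stacking, folding and accessibility are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

#: hydrogen bonds per unordered base pair
_HBONDS = {
    frozenset(("G", "C")): 3,
    frozenset(("A", "U")): 2,
    frozenset(("G", "U")): 1,
    frozenset(("A", "C")): 1,
}

#: inter-nucleotide C1'-C1' distances (nanometers) for the paired steps
_DISTANCE_NM = {
    frozenset(("A", "C")): 1.04,
    frozenset(("G", "C")): 1.03,
    frozenset(("A", "U")): 1.03,
    frozenset(("G", "U")): 1.02,
}

#: maximal bonds a miRNA base can contribute (its Watson-Crick partner)
_MAX_BONDS = {"G": 3, "C": 3, "A": 2, "U": 2}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# integer encoding used by the vectorised scanner
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
BOND_MATRIX = np.zeros((4, 4), dtype=np.int64)
for _pair, _n in _HBONDS.items():
    _b = sorted(_pair)
    _i, _j = _BASE_INDEX[_b[0]], _BASE_INDEX[_b[1]]
    BOND_MATRIX[_i, _j] = _n
    BOND_MATRIX[_j, _i] = _n


def _check_base(b: str) -> str:
    if b not in RNA_ALPHABET:
        raise ValueError(f"base {b!r} outside RNA alphabet {{A,C,G,U}}")
    return b


def count_hbonds(b1: str, b2: str) -> int:
    """Hydrogen bonds formed between two opposing bases (0-3), symmetric."""
    _check_base(b1)
    _check_base(b2)
    return _HBONDS.get(frozenset((b1, b2)), 0)


def pair_distance(b1: str, b2: str) -> Optional[float]:
    """Inter-nucleotide distance in nm for a paired step, None if unpaired."""
    _check_base(b1)
    _check_base(b2)
    return _DISTANCE_NM.get(frozenset((b1, b2)))


def reverse_complement(seq: str) -> str:
    """Exact RNA reverse complement (Watson-Crick)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int array (A=0, C=1, G=2, U=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        pos = int(np.argmax(out < 0))
        raise ValueError(f"non-ACGU character {seq[pos]!r} at position {pos + 1}")
    return out


RatioMode = Literal["bonds", "paired"]


@dataclass(frozen=True)
class EnergyModel:
    """Energy parametrization of the bond-counting duplex model.

    ``k_e`` converts a hydrogen-bond count into kJ/mole.  The default of
    2.4 kJ/mole per bond puts a fully complementary mixed-composition
    24-nt duplex near -150 kJ/mole, the magnitude typical of strong
    sites in published MirTarget-style tables.  All threshold logic in
    the scanner operates on the k_e-invariant ratio, so the absolute
    scale only matters for the energy-threshold association filters.

    ``ratio_mode`` selects how the site-quality ratio is computed:
    ``"bonds"`` (default) is the energy ratio 100*dG/dGm; ``"paired"``
    is the fraction of positions forming any listed pair, which renders
    the 20-of-22-paired calibration as 91%.
    """

    k_e: float = 2.4
    ratio_mode: RatioMode = "bonds"

    def __post_init__(self) -> None:
        if self.k_e <= 0:
            raise ValueError("k_e must be positive")
        if self.ratio_mode not in ("bonds", "paired"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class PairStep:
    """One opposing-base step of a duplex."""

    mrna_base: str
    mirna_base: str
    hbonds: int
    distance_nm: Optional[float]
    paired: bool


@dataclass(frozen=True)
class DuplexScheme:
    """A fully scored gapless duplex.

    ``steps`` run along the mRNA window 5'->3'; step i opposes the
    miRNA base at position length-i counted 5'->3' (antiparallel).
    """

    steps: tuple[PairStep, ...]
    total_hbonds: int
    dG: float
    dGm: float
    ratio_pct: float
    ratio_mode: RatioMode = "bonds"

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def n_paired(self) -> int:
        return sum(1 for s in self.steps if s.paired)

    def render(self) -> str:
        return render_scheme(self)


def max_bond_total(mirna_seq: str) -> int:
    """Bond total of the miRNA against its exact complement (3 per G/C, 2 per A/U)."""
    return sum(_MAX_BONDS[_check_base(b)] for b in mirna_seq)


def dgm(mirna_seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Free energy (kJ/mole) of the miRNA bound to its exact complement."""
    return -model.k_e * max_bond_total(mirna_seq)


def duplex(mirna_seq: str, window: str, model: EnergyModel = DEFAULT_MODEL) -> DuplexScheme:
    """Score the gapless antiparallel duplex of a miRNA against an mRNA window.

    Parameters
    ----------
    mirna_seq : RNA string, 5'->3'
    window : RNA string, 5'->3', same length as the miRNA
    model : energy scale and ratio mode

    Returns
    -------
    DuplexScheme with per-step pairing, total bond count, dG, dGm and
    the site-quality ratio under the model's active mode.
    """
    if len(window) != len(mirna_seq):
        raise ValueError(
            f"window length {len(window)} != miRNA length {len(mirna_seq)}"
        )
    steps = []
    total = 0
    for i, mb in enumerate(window):
        rb = mirna_seq[len(mirna_seq) - 1 - i]  # antiparallel partner
        n = count_hbonds(mb, rb)
        steps.append(
            PairStep(
                mrna_base=mb,
                mirna_base=rb,
                hbonds=n,
                distance_nm=pair_distance(mb, rb) if n else None,
                paired=n > 0,
            )
        )
        total += n
    d_g = -model.k_e * total
    d_gm = dgm(mirna_seq, model)
    if model.ratio_mode == "paired":
        ratio = 100.0 * sum(1 for s in steps if s.paired) / len(steps)
    else:
        ratio = 100.0 * d_g / d_gm  # == 100 * total / max_bond_total
    return DuplexScheme(
        steps=tuple(steps),
        total_hbonds=total,
        dG=d_g,
        dGm=d_gm,
        ratio_pct=ratio,
        ratio_mode=model.ratio_mode,
    )


def render_scheme(scheme: DuplexScheme) -> str:
    """Three-line text rendering: mRNA strand, bond marks, miRNA strand.

    Canonical pairs (2-3 bonds) are marked ``|``, single-bond
    non-canonical pairs ``:``, unpaired steps a space.  The miRNA line
    is printed 3'->5' so opposing bases align by column.
    """
    mrna = "".join(s.mrna_base for s in scheme.steps)
    marks = "".join(
        "|" if s.hbonds >= 2 else (":" if s.hbonds == 1 else " ")
        for s in scheme.steps
    )
    mirna = "".join(s.mirna_base for s in scheme.steps)
    return f"5' {mrna} 3'\n   {marks}\n3' {mirna} 5'"
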