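"""Protein sequences, residue mass tables, tryptic digestion and peptide masses.

Residue masses are the standard monoisotopic and average values for the 20
proteinogenic amino-acid residues (i.e. amino acid minus water), as tabulated
by Unimod / the AMDIS-style references used throughout proteomics software.
All masses are in daltons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "ProteinRecord",
    "ResidueMassTable",
    "ModificationScheme",
    "Peptide",
    "read_fasta",
    "write_fasta",
    "digest",
    "peptide_monoisotopic_mass",
    "protein_average_mass",
    "molar_extinction_280",
    "DEFAULT_MASS_TABLE",
    "DEFAULT_MODS",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: monoisotopic residue masses, Da
_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: average (isotope-abundance weighted) residue masses, Da
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.007276
HYDROGEN = 1.007825
#: spacing between adjacent isotope peaks of a peptide (C13 - C12), Da
ISOTOPE_SPACING = 1.00335


class FastaFormatError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains a non-standard residue letter."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein chain with 1-based residue numbering.

    ``tag_span`` marks an affinity tag (1-based inclusive interval) appended
    to the natural chain; residue numbering and default mass/property
    computations refer to the natural (untagged) sequence, matching the
    Trp90/Tyr218/Met244-style numbering used for catalase-peroxidases.
    """

    id: str
    sequence: str
    description: str = ""
    tag_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _MONO:
                raise SequenceValidationError(
                    f"{self.id}: illegal residue {ch!r} at position {i}"
                )
        if self.tag_span is not None:
            lo, hi = self.tag_span
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise SequenceValidationError(
                    f"{self.id}: tag_span {self.tag_span} outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def untagged_sequence(self) -> str:
        """The natural chain with the affinity tag removed."""
        if self.tag_span is None:
            return self.sequence
        lo, hi = self.tag_span
        return self.sequence[: lo - 1] + self.sequence[hi:]

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position of the natural chain."""
        seq = self.untagged_sequence()
        if not 1 <= position <= len(seq):
            raise IndexError(f"position {position} outside [1, {len(seq)}]")
        return seq[position - 1]


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue masses plus the constants the mass arithmetic needs."""

    monoisotopic: dict[str, float] = field(default_factory=lambda: dict(_MONO))
    average: dict[str, float] = field(default_factory=lambda: dict(_AVG))
    water_monoisotopic: float = WATER_MONO
    water_average: float = WATER_AVG
    proton: float = PROTON
    hydrogen: float = HYDROGEN
    modification_deltas: dict[str, float] = field(
        default_factory=lambda: {
            "carbamidomethyl": 57.02146,
            "oxidation": 15.99491,
        }
    )

    @classmethod
    def from_config(cls, path: str | Path) -> "ResidueMassTable":
        """Override modification deltas from a plain-text ``name = delta`` file."""
        table = cls()
        deltas = dict(table.modification_deltas)
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            name, _, value = line.partition("=")
            deltas[name.strip()] = float(value)
        return cls(modification_deltas=deltas)


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ModificationScheme:
    """Fixed and variable modifications in the MaxQuant convention.

    Default mirrors a standard reduced/alkylated tryptic search:
    carbamidomethylation of Cys fixed, oxidation of Met variable,
    at most two variable modifications per peptide.
    """

    fixed: tuple[tuple[str, float], ...] = (("C", 57.02146),)
    variable: tuple[tuple[str, float], ...] = (("M", 15.99491),)
    max_variable: int = 2

    def __post_init__(self) -> None:
        for residue, delta in self.fixed + self.variable:
            if residue not in _MONO:
                raise SequenceValidationError(f"unknown residue letter {residue!r}")
            if not (delta == delta and abs(delta) < float("inf")):
                raise ValueError(f"non-finite delta for {residue}")


DEFAULT_MODS = ModificationScheme()
NO_MODS = ModificationScheme(fixed=(), variable=(), max_variable=0)


@dataclass(frozen=True)
class Peptide:
    """A fully tryptic peptide, 1-based inclusive coordinates on its parent."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    applied_mods: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.protein_id}[{self.start}-{self.end}]: sequence length "
                f"{len(self.sequence)} does not match coordinates"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Whitespace inside sequence lines is stripped and letters upper-cased.
    Raises :class:`FastaFormatError` on non-FASTA content and
    :class:`SequenceValidationError` on illegal residue letters.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise FastaFormatError(f"{path}: not FASTA, first line: {first!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def cleavage_sites(sequence: str, enzyme: str = "trypsin") -> list[int]:
    """0-based indices i such that the enzyme cleaves between i and i+1."""
    if enzyme != "trypsin":
        raise ValueError(f"unknown enzyme {enzyme!r}; only 'trypsin' is supported")
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    use_tag: bool = False,
) -> list[Peptide]:
    """Fully enzymatic digestion with up to ``max_missed`` missed cleavages.

    Trypsin cleaves C-terminal to K or R except when the next residue is P;
    the protein termini are peptide termini.  Peptides are returned sorted by
    start position, then length.  Positions are 1-based on the natural
    (untagged) chain unless ``use_tag`` is set.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence if use_tag else protein.untagged_sequence()
    sites = cleavage_sites(seq, enzyme)
    # boundaries in 0-based half-open coordinates
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p)))
    return peptides


def apply_fixed_mods(peptide: Peptide, mods: ModificationScheme) -> float:
    """Total mass delta of fixed modifications for a peptide."""
    return sum(
        delta for residue, delta in mods.fixed for ch in peptide.sequence if ch == residue
    )


def variable_mod_combinations(
    peptide: Peptide, mods: ModificationScheme, max_total: int | None = None
) -> list[tuple[tuple[int, str, float], ...]]:
    """All ways of placing <= max_variable variable mods on a peptide.

    Each combination is a tuple of (1-based position in peptide, residue, delta),
    the empty combination first; deterministic order.
    """
    cap = mods.max_variable if max_total is None else min(mods.max_variable, max_total)
    slots = [
        (pos, residue, delta)
        for residue, delta in mods.variable
        for pos, ch in enumerate(peptide.sequence, start=1)
        if ch == residue
    ]
    slots.sort()
    combos: list[tuple[tuple[int, str, float], ...]] = []
    for k in range(0, min(cap, len(slots)) + 1):
        combos.extend(itertools.combinations(slots, k))
    return combos


def peptide_monoisotopic_mass(
    peptide: Peptide,
    mods: ModificationScheme = DEFAULT_MODS,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas.

    Fixed modifications are always applied; variable modifications only if
    recorded in ``peptide.applied_mods``.
    """
    try:
        mass = sum(table.monoisotopic[ch] for ch in peptide.sequence)
    except KeyError as exc:
        raise SequenceValidationError(
            f"residue {exc.args[0]!r} absent from mass table"
        ) from None
    mass += table.water_monoisotopic
    mass += apply_fixed_mods(peptide, mods)
    mass += sum(delta for _, _, delta in peptide.applied_mods)
    return mass


def protein_average_mass(
    protein: ProteinRecord,
    include_tag: bool = False,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Average (isotope-abundance weighted) chain mass in kDa, 3 decimals.

    With ``include_tag=False`` (default) the affinity tag, if annotated, is
    excluded, matching subunit masses quoted for the natural chain.
    """
    seq = protein.sequence if include_tag else protein.untagged_sequence()
    mass = sum(table.average[ch] for ch in seq) + table.water_average
    return round(mass / 1000.0, 3)


def molar_extinction_280(
    protein: ProteinRecord,
    n_cystine: int = 0,
    include_tag: bool = False,
) -> float:
    """Molar extinction coefficient at 280 nm, M^-1 cm^-1 (Gill-von Hippel).

    eps = nW*5500 + nY*1490 + n_cystine*125.  All cysteines are assumed
    reduced by default (``n_cystine=0``), the convention for a
    reduced/alkylated sample.
    """
    seq = protein.sequence if include_tag else protein.untagged_sequence()
    if n_cystine < 0 or 2 * n_cystine > seq.count("C"):
        raise ValueError("n_cystine inconsistent with cysteine count")
    return seq.count("W") * 5500 + seq.count("Y") * 1490 + n_cystine * 125
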