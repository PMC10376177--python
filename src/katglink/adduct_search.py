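"""Candidate enumeration and mass arithmetic for covalent peptide adducts.

A covalent adduct such as the catalase-peroxidase Met-Tyr-Trp crosslink is
described by an ordered chain of residue sites on one protein.  After tryptic
digestion each site lies on one or more peptides (more, when missed cleavages
give alternative boundaries).  A candidate crosslinked species is one choice
of covering peptide per site; its neutral mass is the plain sum of the
component peptide masses ("naive sum") minus two hydrogen atoms per covalent
bond, since each C-C/C-S bond of the adduct forms with loss of 2 H.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .proteoforms import (
    DEFAULT_MODS,
    HYDROGEN,
    PROTON,
    ModificationScheme,
    Peptide,
    ProteinRecord,
    peptide_monoisotopic_mass,
    variable_mod_combinations,
)

__all__ = [
    "AdductSpec",
    "CrosslinkCandidate",
    "TheoreticalIonSeries",
    "MatchReport",
    "enumerate_candidates",
    "corrected_mass",
    "ion_series",
    "match_observed",
]

#: mass lost per covalent bond: two hydrogen atoms, Da
BOND_LOSS = 2.0 * HYDROGEN


class UncoveredSiteError(ValueError):
    """An adduct site not covered by any digested peptide."""


@dataclass(frozen=True)
class AdductSpec:
    """An ordered chain of crosslinked residue sites on one protein.

    ``sites`` are (residue letter, 1-based position) pairs in chain order,
    e.g. ``[("M", 244), ("Y", 218), ("W", 90)]``; ``bond_count`` is the number
    of covalent bonds of the full linear chain (sites - 1).
    """

    protein_id: str
    sites: tuple[tuple[str, int], ...]
    bond_count: int = -1  # -1 -> derived as len(sites) - 1

    def __post_init__(self) -> None:
        positions = [p for _, p in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("adduct site positions must be distinct")
        if self.bond_count == -1:
            object.__setattr__(self, "bond_count", len(self.sites) - 1)
        if self.bond_count != len(self.sites) - 1:
            raise ValueError("bond_count must equal number of sites - 1")

    @classmethod
    def parse(cls, protein_id: str, text: str) -> "AdductSpec":
        """Parse an ``"M244,Y218,W90"``-style site list."""
        sites = []
        for token in text.split(","):
            token = token.strip()
            sites.append((token[0].upper(), int(token[1:])))
        return cls(protein_id=protein_id, sites=tuple(sites))

    def validate_against(self, protein: ProteinRecord) -> None:
        for letter, pos in self.sites:
            actual = protein.residue(pos)
            if actual != letter:
                raise ValueError(
                    f"{protein.id}: expected {letter} at position {pos}, found {actual}"
                )


@dataclass(frozen=True)
class CrosslinkCandidate:
    """One concrete crosslinked species: peptides, bond count, masses."""

    protein_id: str
    site_positions: tuple[int, ...]
    peptides: tuple[Peptide, ...]  # distinct component peptides, sorted by start
    bond_count: int
    naive_sum_mass: float
    corrected_mass: float

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def label(self) -> str:
        parts = "+".join(f"{p.start}-{p.end}" for p in self.peptides)
        mods = sum(len(p.applied_mods) for p in self.peptides)
        suffix = f"+{mods}ox" if mods else ""
        return f"{self.protein_id}:{parts}{suffix}"


@dataclass(frozen=True)
class TheoreticalIonSeries:
    """m/z of the [M + zH]^z+ ion forms over a charge range."""

    neutral_mass: float
    z_min: int
    z_max: int
    mz: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (1 <= self.z_min <= self.z_max):
            raise ValueError("require 1 <= z_min <= z_max")
        if not self.mz:
            values = tuple(
                (self.neutral_mass + z * PROTON) / z
                for z in range(self.z_min, self.z_max + 1)
            )
            object.__setattr__(self, "mz", values)

    @property
    def charges(self) -> range:
        return range(self.z_min, self.z_max + 1)

    def mz_for(self, z: int) -> float:
        return self.mz[z - self.z_min]


def corrected_mass(naive_sum: float, bond_count: int) -> float:
    """Bond-corrected neutral mass: naive sum minus 2 H atoms per bond."""
    if bond_count < 0:
        raise ValueError("bond_count must be >= 0")
    return naive_sum - bond_count * BOND_LOSS


def ion_series(neutral_mass: float, z_min: int, z_max: int) -> TheoreticalIonSeries:
    """[M + zH]^z+ m/z values for z in [z_min, z_max]."""
    return TheoreticalIonSeries(neutral_mass=neutral_mass, z_min=z_min, z_max=z_max)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class MatchReport:
    """Observed deconvoluted mass versus one candidate's theoretical masses."""

    candidate: CrosslinkCandidate
    observed_mass: float
    delta_to_naive: float  # naive sum - observed (positive when mass was lost)
    delta_to_corrected: float  # observed - corrected
    inferred_bond_count: int
    rounded_observed: int
    accepted: bool
    tolerance: float
    evidence: object | None = None


def match_observed(
    observed_mass: float,
    candidate: CrosslinkCandidate,
    tolerance: float = 0.05,
    evidence: object | None = None,
) -> MatchReport:
    """Compare an observed neutral monoisotopic mass with a candidate.

    The number of covalent bonds actually formed is inferred from the mass
    deficit relative to the naive peptide-mass sum (2.01565 Da per bond); the
    match is accepted when the observed mass agrees with the bond-corrected
    theoretical mass within ``tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    delta_naive = candidate.naive_sum_mass - observed_mass
    delta_corr = observed_mass - candidate.corrected_mass
    inferred = _round_half_away(delta_naive / BOND_LOSS)
    return MatchReport(
        candidate=candidate,
        observed_mass=observed_mass,
        delta_to_naive=delta_naive,
        delta_to_corrected=delta_corr,
        inferred_bond_count=inferred,
        rounded_observed=_round_half_away(observed_mass),
        accepted=abs(delta_corr) <= tolerance,
        tolerance=tolerance,
        evidence=evidence,
    )


def _covering_variants(
    peptides: list[Peptide], position: int
) -> list[Peptide]:
    found = sorted(
        (p for p in peptides if p.covers(position)),
        key=lambda p: (p.start, p.end, p.applied_mods),
    )
    if not found:
        raise UncoveredSiteError(f"adduct site at position {position} covered by no peptide")
    return found


def _subchains(
    sites: tuple[tuple[str, int], ...], include_noncontiguous: bool
) -> list[tuple[tuple[str, int], ...]]:
    n = len(sites)
    if n == 1:
        return [sites]
    chains = [
        sites[i : i + length]
        for length in range(2, n + 1)
        for i in range(n - length + 1)
    ]
    if include_noncontiguous:
        contiguous = set(chains)
        for length in range(2, n + 1):
            for combo in itertools.combinations(sites, length):
                if combo not in contiguous:
                    chains.append(combo)
    return chains


def enumerate_candidates(
    peptides: list[Peptide],
    spec: AdductSpec,
    mods: ModificationScheme = DEFAULT_MODS,
    include_noncontiguous: bool = False,
    max_variable_per_candidate: int = 2,
) -> list[CrosslinkCandidate]:
    """All candidate crosslinked species for an adduct chain.

    For the full chain and every contiguous sub-chain (the species observed in
    practice include both the full Met-Tyr-Trp triple and a two-peptide pair),
    one candidate is emitted per way of choosing a covering peptide for each
    site; a peptide covering several sites is counted once.  Variable
    modifications expand candidates up to ``max_variable_per_candidate`` total.
    Order is deterministic.
    """
    base_by_position: dict[int, list[Peptide]] = {}
    for _, pos in spec.sites:
        base_by_position[pos] = _covering_variants(peptides, pos)

    candidates: list[CrosslinkCandidate] = []
    for chain in _subchains(spec.sites, include_noncontiguous):
        positions = tuple(pos for _, pos in chain)
        bond_count = len(chain) - 1
        for choice in itertools.product(*(base_by_position[p] for p in positions)):
            # collapse one peptide covering several sites
            distinct: list[Peptide] = []
            for pep in choice:
                if pep not in distinct:
                    distinct.append(pep)
            # a site chain must map consistently: a collapsed peptide pair is
            # fine, but two *different* overlapping peptides covering the same
            # site choice would double-count residues -> skip such choices
            if _has_conflicting_overlap(distinct):
                continue
            distinct.sort(key=lambda p: (p.start, p.end))
            for modded in _expand_variable_mods(
                distinct, mods, max_variable_per_candidate
            ):
                naive = sum(peptide_monoisotopic_mass(p, mods) for p in modded)
                candidates.append(
                    CrosslinkCandidate(
                        protein_id=spec.protein_id,
                        site_positions=positions,
                        peptides=tuple(modded),
                        bond_count=bond_count,
                        naive_sum_mass=naive,
                        corrected_mass=corrected_mass(naive, bond_count),
                    )
                )
    candidates.sort(
        key=lambda c: (
            len(c.site_positions),
            c.site_positions,
            tuple((p.start, p.end, p.applied_mods) for p in c.peptides),
        )
    )
    return candidates


def _has_conflicting_overlap(peptides: list[Peptide]) -> bool:
    for a, b in itertools.combinations(peptides, 2):
        if a.start <= b.end and b.start <= a.end:
            return True
    return False


def _expand_variable_mods(
    peptides: list[Peptide], mods: ModificationScheme, max_total: int
) -> list[tuple[Peptide, ...]]:
    per_peptide = [variable_mod_combinations(p, mods, max_total) for p in peptides]
    out = []
    for combo in itertools.product(*per_peptide):
        if sum(len(c) for c in combo) > max_total:
            continue
        out.append(
            tuple(
                Peptide(
                    protein_id=p.protein_id,
                    start=p.start,
                    end=p.end,
                    sequence=p.sequence,
                    missed_cleavages=p.missed_cleavages,
                    applied_mods=c,
                )
                for p, c in zip(peptides, combo)
            )
        )
    return out
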