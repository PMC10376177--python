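"""Crosslink candidate enumeration, bond-corrected masses and ion series."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from katglink.adduct_search import (
    BOND_LOSS,
    AdductSpec,
    UncoveredSiteError,
    corrected_mass,
    enumerate_candidates,
    ion_series,
    match_observed,
)
from katglink.proteoforms import (
    NO_MODS,
    DEFAULT_MODS,
    PROTON,
    ProteinRecord,
    digest,
    peptide_monoisotopic_mass,
)


class TestAdductSpec:
    def test_parse(self):
        spec = AdductSpec.parse("p", "M244, Y218, W90")
        assert spec.sites == (("M", 244), ("Y", 218), ("W", 90))
        assert spec.bond_count == 2

    def test_rejects_duplicate_positions(self):
        with pytest.raises(ValueError, match="distinct"):
            AdductSpec("p", (("M", 5), ("Y", 5)))

    def test_validate_against_sequence(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        AdductSpec.parse("p", "W2,Y5,M8").validate_against(prot)
        with pytest.raises(ValueError, match="expected Y at position 4"):
            AdductSpec.parse("p", "W2,Y4").validate_against(prot)


class TestCorrectedMass:
    def test_two_bonds(self):
        assert corrected_mass(6000.0, 2) == pytest.approx(5995.96870, abs=1e-5)

    def test_identity_without_bonds(self):
        assert corrected_mass(6000.0, 0) == 6000.0

    def test_negative_bonds_rejected(self):
        with pytest.raises(ValueError):
            corrected_mass(6000.0, -1)

    def test_rounded_loss_is_4_da_for_two_bonds(self):
        naive = 6520.0313
        assert round(naive - corrected_mass(naive, 2)) == 4
        assert round(naive - corrected_mass(naive, 1)) == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(naive=st.floats(100, 1e5), bonds=st.integers(0, 5))
    def test_constant_step_in_bond_count(self, naive, bonds):
        assert corrected_mass(naive, bonds + 1) - corrected_mass(naive, bonds) == (
            pytest.approx(-2.01565, abs=1e-9)
        )


class TestIonSeries:
    def test_singly_protonated(self):
        assert ion_series(1000.0, 1, 1).mz[0] == pytest.approx(1001.007276, abs=1e-6)

    def test_quadruply_charged_crosslink(self):
        assert ion_series(5995.9687, 4, 4).mz[0] == pytest.approx(1499.999451, abs=1e-6)

    def test_strictly_decreasing_in_charge(self):
        mz = ion_series(1000.0, 1, 3).mz
        assert all(a > b for a, b in zip(mz, mz[1:]))

    def test_invalid_charges(self):
        with pytest.raises(ValueError):
            ion_series(1000.0, 0, 3)
        with pytest.raises(ValueError):
            ion_series(1000.0, 5, 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mass=st.floats(100, 1e5), z=st.integers(1, 12))
    def test_round_trip_inverts_to_neutral_mass(self, mass, z):
        mz = ion_series(mass, z, z).mz[0]
        assert abs(z * mz - z * PROTON - mass) < 1e-9


class TestMatchObserved:
    def _candidate(self, protein):
        peptides = digest(protein, max_missed=0)
        spec = AdductSpec.parse(protein.id, "W2,Y5,M8")
        return enumerate_candidates(peptides, spec, NO_MODS)

    def test_accepts_bond_corrected_mass(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        cand = [c for c in self._candidate(prot) if len(c.site_positions) == 3][0]
        observed = cand.naive_sum_mass - 2 * BOND_LOSS / 2 * 2  # two bonds lost
        report = match_observed(observed, cand, tolerance=0.05)
        assert report.accepted
        assert report.inferred_bond_count == 2

    def test_rejects_naive_mass(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        cand = [c for c in self._candidate(prot) if len(c.site_positions) == 3][0]
        report = match_observed(cand.naive_sum_mass, cand, tolerance=0.05)
        assert not report.accepted
        assert report.inferred_bond_count == 0
        assert abs(report.delta_to_naive) < 1e-9

    def test_integer_rounding_convention(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        pair = [c for c in self._candidate(prot) if len(c.site_positions) == 2][0]
        observed = pair.corrected_mass
        report = match_observed(observed, pair, tolerance=0.05)
        # one covalent bond: naive and corrected masses differ by 2 Da rounded
        assert round(report.delta_to_naive) == 2
        assert report.rounded_observed == round(observed)


class TestEnumerateCandidates:
    def test_three_sites_one_peptide_each(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        peptides = digest(prot, max_missed=0)
        cands = enumerate_candidates(peptides, AdductSpec.parse("p", "W2,Y5,M8"), NO_MODS)
        triples = [c for c in cands if len(c.site_positions) == 3]
        pairs = [c for c in cands if len(c.site_positions) == 2]
        assert len(triples) == 1 and len(pairs) == 2
        assert triples[0].bond_count == 2
        assert all(p.bond_count == 1 for p in pairs)

    def test_missed_cleavage_multiplies_candidates(self):
        prot = ProteinRecord("p", "GWKGYKGMKA")
        cands0 = enumerate_candidates(
            digest(prot, max_missed=0), AdductSpec.parse("p", "W2,Y5,M8"), NO_MODS
        )
        cands1 = enumerate_candidates(
            digest(prot, max_missed=1), AdductSpec.parse("p", "W2,Y5,M8"), NO_MODS
        )
        n3_0 = sum(len(c.site_positions) == 3 for c in cands0)
        n3_1 = sum(len(c.site_positions) == 3 for c in cands1)
        assert n3_0 == 1 and n3_1 > n3_0

    def test_single_site_reduces_to_plain_peptide_search(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        peptides = digest(prot, max_missed=0)
        cands = enumerate_candidates(peptides, AdductSpec("p", (("W", 2),)), NO_MODS)
        assert all(c.bond_count == 0 for c in cands)
        assert all(c.corrected_mass == c.naive_sum_mass for c in cands)

    def test_uncovered_site_error_names_position(self):
        prot = ProteinRecord("p", "GWKGYKGMK")
        peptides = [p for p in digest(prot, max_missed=0) if not p.covers(5)]
        with pytest.raises(UncoveredSiteError, match="position 5"):
            enumerate_candidates(peptides, AdductSpec.parse("p", "W2,Y5,M8"), NO_MODS)

    def test_shared_peptide_collapsed(self):
        # one missed cleavage lets W2 and Y5 sit on a single peptide GWKGYK
        prot = ProteinRecord("p", "GWKGYKGMK")
        peptides = digest(prot, max_missed=1)
        cands = enumerate_candidates(peptides, AdductSpec.parse("p", "W2,Y5"), NO_MODS)
        collapsed = [c for c in cands if c.n_peptides == 1]
        assert collapsed
        for c in collapsed:
            assert c.bond_count == 1  # the intra-peptide bond still loses 2H
            assert c.corrected_mass == pytest.approx(c.naive_sum_mass - 2.01565, abs=1e-9)

    def test_mass_equals_component_sum_minus_bond_loss(self, thermo_standin):
        peptides = digest(thermo_standin, max_missed=2)
        spec = AdductSpec.parse(thermo_standin.id, "M244,Y218,W90")
        for cand in enumerate_candidates(peptides, spec, DEFAULT_MODS):
            parts = sum(peptide_monoisotopic_mass(p, DEFAULT_MODS) for p in cand.peptides)
            assert cand.naive_sum_mass == pytest.approx(parts, abs=1e-9)
            assert cand.corrected_mass == pytest.approx(
                parts - cand.bond_count * BOND_LOSS, abs=1e-9
            )

    def test_count_matches_product_rule(self):
        # brute-force: candidate count per sub-chain is the product of the
        # number of covering peptides per site (no mods, no overlaps)
        rng = np.random.default_rng(5)
        letters = np.array(list("ACDEFGHILMNQSTVWYKR"))
        for _ in range(20):
            seq = "".join(rng.choice(letters, size=60))
            prot = ProteinRecord("p", seq)
            positions = sorted(rng.choice(np.arange(1, 61), size=3, replace=False))
            sites = tuple((seq[p - 1], int(p)) for p in positions)
            if len({p for _, p in sites}) < 3:
                continue
            peptides = digest(prot, max_missed=2)
            spec = AdductSpec("p", sites)
            cands = enumerate_candidates(peptides, spec, NO_MODS)
            for chain_len in (2, 3):
                chains = [
                    sites[i : i + chain_len] for i in range(3 - chain_len + 1)
                ]
                expected = 0
                for chain in chains:
                    combos = itertools.product(
                        *[[p for p in peptides if p.covers(pos)] for _, pos in chain]
                    )
                    for combo in combos:
                        distinct = []
                        for pep in combo:
                            if pep not in distinct:
                                distinct.append(pep)
                        overlap = any(
                            a.start <= b.end and b.start <= a.end
                            for a, b in itertools.combinations(distinct, 2)
                        )
                        if not overlap:
                            expected += 1
                got = sum(len(c.site_positions) == chain_len for c in cands)
                assert got == expected

    def test_deterministic_order(self, thermo_standin):
        peptides = digest(thermo_standin, max_missed=2)
        spec = AdductSpec.parse(thermo_standin.id, "M244,Y218,W90")
        a = enumerate_candidates(peptides, spec, DEFAULT_MODS)
        b = enumerate_candidates(peptides, spec, DEFAULT_MODS)
        assert [c.label() for c in a] == [c.label() for c in b]

    def test_variable_mods_expand_candidates(self):
        prot = ProteinRecord("p", "GWKGYKGMK")  # Met at site 8 can oxidise
        peptides = digest(prot, max_missed=0)
        spec = AdductSpec.parse("p", "W2,Y5,M8")
        plain = enumerate_candidates(peptides, spec, NO_MODS)
        modded = enumerate_candidates(peptides, spec, DEFAULT_MODS)
        assert len(modded) > len(plain)
        base_triple = [c for c in plain if len(c.site_positions) == 3][0]
        deltas = {
            round(c.naive_sum_mass - base_triple.naive_sum_mass, 5)
            for c in modded
            if c.site_positions == base_triple.site_positions
        }
        assert 15.99491 in deltas
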