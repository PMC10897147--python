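"""Elemental composition and isotopologue envelope checks.

The convolution path is validated against exhaustive isotopologue
enumeration, an independent residue-mass table (pyteomics), and closed-form
mass-shift identities of the labeling chemistry.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_envelope
from turnoverms.constants import N15_SHIFT
from turnoverms.isotope import (
    BUILTIN_MODS,
    LabelScheme,
    composition,
    envelope,
    mean_mass,
    mix,
)


class TestComposition:
    def test_glycylglycine_formula(self):
        c = composition("GG")
        assert (c.C, c.H, c.N, c.O, c.S) == (4, 8, 2, 3, 0)

    @pytest.mark.parametrize("seq", ["ACDK", "CCGVR", "MCPTY"])
    def test_carbamidomethyl_adds_57_per_cysteine(self, seq):
        plain = composition(seq).monoisotopic_mass
        modified = composition(seq, [BUILTIN_MODS["carbamidomethyl"]])
        n_cys = seq.count("C")
        assert modified.monoisotopic_mass - plain == pytest.approx(
            57.02146 * n_cys, abs=1e-4
        )

    def test_tmt_labels_lysines_and_n_terminus(self):
        plain = composition("AKPK").monoisotopic_mass
        tagged = composition("AKPK", [BUILTIN_MODS["tmt10"]]).monoisotopic_mass
        assert tagged - plain == pytest.approx(229.1629 * 3, abs=1e-3)

    def test_bracketed_delta_matches_builtin_tmt(self):
        assert composition("AK[229.1629]").monoisotopic_mass - composition(
            "AK"
        ).monoisotopic_mass == pytest.approx(229.1629, abs=1e-3)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            composition("AXZ")

    def test_mod_with_no_target_site_rejected(self):
        with pytest.raises(ValueError, match="no site"):
            composition("GAV", [BUILTIN_MODS["carbamidomethyl"]])

    def test_monoisotopic_mass_matches_pyteomics(self):
        # independent residue-mass table as cross-check
        from pyteomics import mass as pmass

        for seq in ["PEPTIDE", "ELVISLIVESK", "WCNQMR"]:
            ours = composition(seq).monoisotopic_mass
            ref = pmass.calculate_mass(sequence=seq, monoisotopic=True)
            assert ours == pytest.approx(ref, abs=5e-4)


class TestEnvelope:
    def test_peptide_neutral_monoisotopic_mass(self):
        env = envelope(composition("PEPTIDE"), LabelScheme.natural(), charge=0)
        assert env.mz[0] == pytest.approx(799.35996, abs=5e-5)

    def test_n15_at_natural_abundance_degenerates_to_natural(self):
        comp = composition("SAMPLER")
        nat = envelope(comp, LabelScheme.natural(), charge=0)
        deg = envelope(comp, LabelScheme.nitrogen15(0.00364), charge=0)
        assert np.allclose(nat.abundance, deg.abundance, atol=1e-12)
        assert np.allclose(nat.mz, deg.mz, atol=1e-9)

    def test_full_n15_shifts_monoisotopic_by_nitrogen_count(self):
        comp = composition("PEPTIDE")  # 7 nitrogens
        nat = envelope(comp, LabelScheme.natural(), charge=0)
        full = envelope(comp, LabelScheme.nitrogen15(1.0), charge=0)
        assert full.mz[0] - nat.mz[0] == pytest.approx(7 * 0.9970349, abs=1e-6)

    def test_c13_lysine_is_a_pure_six_carbon_shift(self):
        comp = composition("SAMPLEK")
        nat = envelope(comp, LabelScheme.natural(), charge=0)
        heavy = envelope(comp, LabelScheme.lys_c13(1), charge=0)
        assert heavy.mz[0] - nat.mz[0] == pytest.approx(6.020129, abs=1e-6)

    def test_more_labeled_lysines_than_present_rejected(self):
        with pytest.raises(ValueError, match="lysine"):
            envelope(composition("SAMPLEK"), LabelScheme.lys_c13(2))

    @pytest.mark.parametrize("bad_trunc", [0.0, 1.0, -0.5])
    def test_truncation_threshold_bounds(self, bad_trunc):
        with pytest.raises(ValueError, match="trunc"):
            envelope(composition("GG"), trunc=bad_trunc)

    def test_negative_charge_rejected(self):
        with pytest.raises(ValueError, match="charge"):
            envelope(composition("GG"), charge=-1)

    @pytest.mark.parametrize(
        "seq,scheme",
        [
            ("GG", LabelScheme.natural()),
            ("CMKW", LabelScheme.natural()),
            ("PESTR", LabelScheme.nitrogen15(0.96)),
            ("MYHQEK", LabelScheme.nitrogen15(0.5)),
        ],
    )
    def test_convolution_matches_exhaustive_enumeration(self, seq, scheme):
        comp = composition(seq)
        env = envelope(comp, scheme, charge=0, trunc=1e-15)
        p = scheme.enrichment if scheme.variant == "n15" else None
        oracle = brute_force_envelope(comp.counts, p)
        base = comp.monoisotopic_mass  # all-lightest isotopologue
        for m, a in zip(env.mz, env.abundance):
            shift = int(round(m - base))
            ref_a, ref_dm = oracle[shift]
            assert a == pytest.approx(ref_a, abs=1e-10)
            assert m - base == pytest.approx(ref_dm, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=20),
        p=st.floats(0.05, 1.0),
        charge=st.integers(0, 4),
    )
    def test_abundances_always_sum_to_one(self, seq, p, charge):
        env = envelope(composition(seq), LabelScheme.nitrogen15(p), charge=charge)
        assert abs(env.abundance.sum() - 1.0) <= 1e-9
        assert np.all(np.diff(env.mz) > 0)


class TestMeanMass:
    def test_single_line_envelope(self):
        env = envelope(composition("G"), trunc=0.5)  # keeps only the base line
        assert mean_mass(env) == pytest.approx(env.mz[0])

    def test_two_equal_lines_average(self):
        from turnoverms.isotope import IsotopeEnvelope

        env = IsotopeEnvelope(np.array([100.0, 101.0]), np.array([0.5, 0.5]))
        assert mean_mass(env) == pytest.approx(100.5)

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.9])
    def test_linearity_in_enrichment(self, p):
        comp = composition("PEPTIDEK")  # 9 nitrogens (K side chain has one more)
        nat = envelope(comp, LabelScheme.natural(), charge=0, trunc=1e-12)
        enr = envelope(comp, LabelScheme.nitrogen15(p), charge=0, trunc=1e-12)
        expected = comp.N * N15_SHIFT * (p - 0.00364)
        assert mean_mass(enr) - mean_mass(nat) == pytest.approx(expected, abs=1e-6)


class TestMix:
    @pytest.fixture
    def pair(self):
        comp = composition("TINYK")
        return (
            envelope(comp, LabelScheme.natural(), charge=2),
            envelope(comp, LabelScheme.nitrogen15(0.96), charge=2),
        )

    def test_w_one_returns_old_exactly(self, pair):
        old, new = pair
        mixed = mix(1.0, old, new)
        assert np.array_equal(mixed.mz, old.mz)
        assert np.allclose(mixed.abundance, old.abundance, atol=1e-12)

    def test_w_zero_returns_new_exactly(self, pair):
        old, new = pair
        mixed = mix(0.0, old, new)
        assert np.array_equal(mixed.mz, new.mz)
        assert np.allclose(mixed.abundance, new.abundance, atol=1e-12)

    def test_half_mix_on_disjoint_grids_halves_both(self, pair):
        old, new = pair
        mixed = mix(0.5, old, new)
        for m, a in zip(old.mz, old.abundance):
            j = np.argmin(np.abs(mixed.mz - m))
            assert mixed.abundance[j] == pytest.approx(0.5 * a, abs=1e-12)

    def test_charge_mismatch_rejected(self, pair):
        old, _ = pair
        other = envelope(composition("TINYK"), LabelScheme.natural(), charge=3)
        with pytest.raises(ValueError, match="charge"):
            mix(0.5, old, other)
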