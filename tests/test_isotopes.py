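import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zoomsid.isotopes import (
    GRID_STEP,
    ISOTOPES,
    PROTON_MASS,
    ElementalComposition,
    IsotopePattern,
    elemental_composition,
    isotope_pattern,
    monoisotopic_mh,
    pattern_for_variant,
    render_template,
)
from zoomsid.markers import peptide_from_sequence
from zoomsid.ptm import HYDROXYLATION_MASS, PeptideVariant

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA, min_size=1, max_size=40)


class TestComposition:
    def test_single_glycine_with_water_termini(self):
        assert elemental_composition("G") == ElementalComposition(2, 5, 1, 2, 0)

    def test_residue_additivity(self):
        assert elemental_composition("GG") == ElementalComposition(4, 8, 2, 3, 0)

    def test_hydroxylation_adds_one_oxygen(self):
        base = elemental_composition("GPAGPK")
        hyd = elemental_composition("GPAGPK", n_hydroxyl=1)
        assert (hyd.O - base.O, hyd.C - base.C, hyd.H - base.H) == (1, 0, 0)
        assert hyd.monoisotopic_mass() - base.monoisotopic_mass() == pytest.approx(
            HYDROXYLATION_MASS, abs=1e-9)

    def test_chemical_deamidation_swaps_nh_for_o(self):
        base = elemental_composition("TGQPGAVGPAGIR")
        deam = elemental_composition("TGQPGAVGPAGIR", n_deamidated_q=1)
        assert (deam.N - base.N, deam.H - base.H, deam.O - base.O) == (-1, -1, 1)

    def test_unknown_residue_is_reported(self):
        with pytest.raises(ValueError, match="'X' at position 2"):
            elemental_composition("GXG")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(peptides)
    def test_mh_matches_pyteomics(self, seq):
        from pyteomics import mass as pt_mass

        expected = pt_mass.calculate_mass(sequence=seq, charge=0) + 1.007276
        assert monoisotopic_mh(seq) == pytest.approx(expected, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(peptides, peptides)
    def test_mh_additive_over_concatenation(self, a, b):
        water = elemental_composition("G").monoisotopic_mass() - \
            elemental_composition("GG").monoisotopic_mass() + \
            elemental_composition("G").monoisotopic_mass()
        lhs = monoisotopic_mh(a + b)
        rhs = monoisotopic_mh(a) + monoisotopic_mh(b) - water - PROTON_MASS
        assert lhs == pytest.approx(rhs, abs=1e-9)


def brute_force_pattern(comp, mass_offset=0.0):
    """Exhaustive isotopologue enumeration for small formulas."""
    dists = []
    for elem in ("C", "H", "N", "O", "S"):
        for _ in range(getattr(comp, elem)):
            dists.append(ISOTOPES[elem])
    agg = {}  # nominal shift -> [prob, prob-weighted mass]
    base = sum(d[0][0] for d in dists)
    for combo in itertools.product(*[range(len(d)) for d in dists]):
        mass = prob = 0.0
        prob = 1.0
        for d, k in zip(dists, combo):
            mass += d[k][0]
            prob *= d[k][1] / sum(a for _, a in d)
        key = round(mass - base)
        p, wm = agg.get(key, (0.0, 0.0))
        agg[key] = (p + prob, wm + prob * mass)
    peaks = sorted((wm / p + mass_offset, p) for k, (p, wm) in agg.items())
    top = max(p for _, p in peaks)
    return [(m, p / top) for m, p in peaks]


class TestIsotopePattern:
    def test_single_carbon_ratio(self):
        pat = isotope_pattern(ElementalComposition(1, 0, 0, 0, 0), mass_offset=0.0)
        assert len(pat.peaks) == 2
        assert pat.peaks[0][1] == 1.0
        assert pat.peaks[1][1] == pytest.approx(0.0107 / 0.9893, rel=1e-6)

    def test_small_peptide_matches_exhaustive_enumeration(self):
        comp = elemental_composition("GG")  # C4 H8 N2 O3
        pat = isotope_pattern(comp, prune=1e-6, mass_offset=0.0)
        expected = brute_force_pattern(comp)
        for (m, a), (em, ea) in zip(pat.peaks, expected[: len(pat.peaks)]):
            assert m == pytest.approx(em, abs=1e-6)
            assert a == pytest.approx(ea, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.text(alphabet=AA, min_size=5, max_size=35))
    def test_peak_spacing_near_one_dalton(self, seq):
        pat = isotope_pattern(elemental_composition(seq))
        masses = pat.masses
        assert np.all(np.diff(masses) >= 0.99) and np.all(np.diff(masses) <= 1.01)

    def test_first_peak_equals_monoisotopic_mh(self):
        pep = peptide_from_sequence("TGQPGAVGPAGIR")
        var = PeptideVariant(pep, 1, False, 1.0,
                             monoisotopic_mh("TGQPGAVGPAGIR", 1))
        pat = pattern_for_variant(var)
        assert pat.peaks[0][0] == pytest.approx(var.mass_mh, abs=1e-4)

    def test_unit_spacing_mode_forces_exact_ladder(self):
        from zoomsid.config import IsotopeConfig

        pep = peptide_from_sequence("TGQPGAVGPAGIR")
        var = PeptideVariant(pep, 0, False, 1.0, monoisotopic_mh("TGQPGAVGPAGIR"))
        pat = pattern_for_variant(var, IsotopeConfig(true_spacing=False))
        assert np.allclose(np.diff(pat.masses), 1.0)

    def test_prune_and_cap_limit_peak_count(self):
        comp = elemental_composition("GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR" * 2)
        pat = isotope_pattern(comp, prune=1e-3, max_peaks=10)
        assert len(pat.peaks) <= 10
        assert min(a for _, a in pat.peaks) >= 1e-3


class TestRenderTemplate:
    def _stick(self, *peaks):
        return IsotopePattern(tuple(peaks))

    def test_single_stick_peaks_at_nearest_grid_point(self):
        t = render_template(self._stick((1200.003, 1.0)), sigma=0.1)
        peak_mass = t.masses[np.argmax(t.values)]
        assert abs(peak_mass - 1200.003) <= GRID_STEP / 2 + 1e-9
        assert t.values.max() == 1.0

    def test_two_sticks_leave_a_valley(self):
        t = render_template(self._stick((1000.0, 1.0), (1001.0, 0.6)), sigma=0.1)
        m = t.masses
        mid = t.values[(m > 1000.3) & (m < 1000.7)].min()
        # analytic two-Gaussian sum at the midpoint is far below the smaller peak
        assert mid < 0.5 * 0.6

    def test_wider_sigma_never_deepens_valleys(self):
        sticks = self._stick((1000.0, 1.0), (1001.0, 0.8))
        narrow = render_template(sticks, sigma=0.1)
        wide = render_template(sticks, sigma=0.2)

        def valley(t):
            sel = (t.masses > 1000.2) & (t.masses < 1000.8)
            return t.values[sel].min()

        assert valley(wide) >= valley(narrow)

    def test_grid_registration_and_margins(self):
        t = render_template(self._stick((1500.037, 1.0)), sigma=0.1)
        assert t.step == GRID_STEP
        assert round(t.start_mass / GRID_STEP) == pytest.approx(
            t.start_mass / GRID_STEP, abs=1e-6)
        assert t.start_mass <= 1500.037 - 1.5
        assert t.end_mass >= 1500.037 + 1.5
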