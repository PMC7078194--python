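"""Isotopologue mass engine, peak assignment and natural-abundance correction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glnfate.isotope_core import (
    DEFAULT_ISOTOPES,
    DELTA_13C,
    DELTA_15N,
    CentroidPeakList,
    IsotopologueState,
    MIDGrid,
    ResolutionModel,
    assign_peaks,
    build_correction,
    correct_mid,
    enumerate_grid,
    forward_convolve,
    isotopologue_mz,
    merge_groups,
    molecule_labeled_fraction,
    monoisotopic_mass,
    parse_formula,
    percent_labeled,
    separability,
    validate_isotope_table,
)

from conftest import PANEL_FORMULAS, brute_force_isotopologue_mass


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C5H10N2O3", {"C": 5, "H": 10, "N": 2, "O": 3}),  # glutamine
            ("C4H4O4", {"C": 4, "H": 4, "O": 4}),  # fumarate
            ("C10H13N4O8P", {"C": 10, "H": 13, "N": 4, "O": 8, "P": 1}),  # IMP
        ],
    )
    def test_known_compositions(self, text, expected):
        assert parse_formula(text).counts == expected

    @pytest.mark.parametrize("bad", ["C5Xe2", "", "5C", "C5H-3", "c5h10"])
    def test_rejects_malformed_or_unknown(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestIsotopologueMass:
    def test_glutamine_monoisotopic(self):
        t = isotopologue_mz(parse_formula("C5H10N2O3"), IsotopologueState(0, 0))
        assert t.neutral_mass == pytest.approx(146.069142, abs=1e-6)

    def test_glutamine_fully_labeled(self):
        t = isotopologue_mz(parse_formula("C5H10N2O3"), IsotopologueState(5, 2))
        assert t.neutral_mass == pytest.approx(153.079986, abs=1e-6)

    def test_mass_defect_gap_constant_across_formulas(self):
        # the 13C - 15N single-substitution gap is a physical constant
        for text in PANEL_FORMULAS.values():
            f = parse_formula(text)
            if f.n_nitrogen == 0:
                continue
            a = isotopologue_mz(f, IsotopologueState(1, 0)).neutral_mass
            b = isotopologue_mz(f, IsotopologueState(0, 1)).neutral_mass
            assert a - b == pytest.approx(0.0063199, abs=1e-6)

    def test_mass_additivity_against_per_atom_oracle(self):
        # every state of every panel metabolite vs a brute-force atom sum
        for name, text in PANEL_FORMULAS.items():
            f = parse_formula(text)
            for c in range(f.n_carbon + 1):
                for n in range(f.n_nitrogen + 1):
                    got = isotopologue_mz(f, IsotopologueState(c, n)).neutral_mass
                    want = brute_force_isotopologue_mass(text, c, n)
                    assert got == pytest.approx(want, abs=1e-6), (name, c, n)

    def test_ion_conventions(self):
        f = parse_formula("C5H9NO4")  # glutamate
        m = isotopologue_mz(f, IsotopologueState(0, 0)).neutral_mass
        neg = isotopologue_mz(f, IsotopologueState(0, 0), charge=-1)
        pos = isotopologue_mz(f, IsotopologueState(0, 0), charge=+1)
        assert neg.mz == pytest.approx(m - 1.00727646, abs=1e-9)
        assert pos.mz == pytest.approx(m + 1.00727646, abs=1e-9)

    def test_out_of_bounds_state(self):
        with pytest.raises(ValueError):
            isotopologue_mz(parse_formula("C4H4O4"), IsotopologueState(0, 1))


class TestSeparability:
    def test_glutamate_13c_vs_15n_resolved_at_instrument_setting(self, orbitrap):
        f = parse_formula("C5H9NO4")
        a = isotopologue_mz(f, IsotopologueState(1, 0), charge=-1).mz
        b = isotopologue_mz(f, IsotopologueState(0, 1), charge=-1).mz
        required, resolved = separability(a, b, orbitrap)
        # direct evaluation of the two formulas
        mean = 0.5 * (a + b)
        assert required == pytest.approx(mean / abs(a - b), rel=1e-12)
        assert required == pytest.approx(2.31e4, rel=0.02)
        assert orbitrap.resolving_power(mean) == pytest.approx(70000 * (200 / mean) ** 0.5)
        assert resolved

    def test_identical_masses_error(self, orbitrap):
        with pytest.raises(ValueError):
            separability(146.0, 146.0, orbitrap)

    def test_boundary_exactly_one_fwhm_is_resolved(self):
        # separation factor 1, gap exactly equal to FWHM: >= convention
        model = ResolutionModel(r_ref=1000.0, mz_ref=100.0, exponent=0.0)
        mza = 100.0 - 0.05
        mzb = 100.0 + 0.05  # gap 0.1 = 100/1000
        required, resolved = separability(mza, mzb, model)
        assert required == pytest.approx(1000.0)
        assert resolved


class TestEnumerateGrid:
    def test_grid_sizes(self):
        gln = parse_formula("C5H10N2O3")
        assert len(enumerate_grid(gln, 5, 2, charge=-1)) == 18
        fum = parse_formula("C4H4O4")
        assert len(enumerate_grid(fum, 4, 0, charge=-1)) == 5

    def test_grid_sorted_by_mz(self):
        grid = enumerate_grid(parse_formula("C10H13N4O8P"), 10, 4, charge=-1)
        mzs = [t.mz for t in grid]
        assert mzs == sorted(mzs)

    def test_bounds_exceeded(self):
        with pytest.raises(ValueError):
            enumerate_grid(parse_formula("C5H10N2O3"), 5, 3, charge=-1)

    def test_merge_groups_flags_subresolution_pairs(self):
        # at m/z ~347 the 13C/15N gap (0.00632 Da) is below the FWHM of a
        # 70k@200 instrument, so mixed states collapse into merged groups
        imp = parse_formula("C10H13N4O8P")
        grid = enumerate_grid(imp, 2, 2, charge=-1)
        low = merge_groups(grid, ResolutionModel())
        high = merge_groups(grid, ResolutionModel(r_ref=1e9))
        assert any(len(g) > 1 for g in low)
        assert all(len(g) == 1 for g in high)


class TestAssignPeaks:
    def _grid(self):
        return enumerate_grid(parse_formula("C5H10N2O3"), 5, 2, charge=+1)

    def test_single_peak_at_m0(self):
        grid = self._grid()
        m0 = next(t for t in grid if t.state == (0, 0))
        peaks = CentroidPeakList("s", 0.0, np.array([m0.mz]), np.array([100.0]))
        asn = assign_peaks(peaks, grid, tolerance_ppm=5.0)
        assert asn.mid.f[0, 0] == pytest.approx(1.0)
        assert not asn.unassigned

    def test_peak_outside_tolerance_unassigned(self):
        grid = self._grid()
        m0 = next(t for t in grid if t.state == (0, 0))
        off = m0.mz * (1 + 6e-6)  # 6 ppm away
        peaks = CentroidPeakList("s", 0.0, np.array([off]), np.array([100.0]))
        with pytest.warns(UserWarning):
            asn = assign_peaks(peaks, grid, tolerance_ppm=5.0)
        assert asn.unassigned == [0]
        assert asn.mid.total == 0.0

    def test_ambiguous_peak_goes_to_nearest_and_is_flagged(self):
        grid = self._grid()
        t10 = next(t for t in grid if t.state == (1, 0))
        t01 = next(t for t in grid if t.state == (0, 1))
        mz = t01.mz + 0.3 * (t10.mz - t01.mz)  # nearer the 15N1 species
        peaks = CentroidPeakList("s", 0.0, np.array([mz]), np.array([50.0]))
        asn = assign_peaks(peaks, grid, tolerance_ppm=60.0)
        assert asn.ambiguous == [0]
        assert asn.mid.f[0, 1] == pytest.approx(1.0)


class TestCorrection:
    def test_zero_abundance_gives_identity(self):
        table = {el: [(m, 1.0)] for el, (m, *_) in
                 {k: v[0] for k, v in DEFAULT_ISOTOPES.items()}.items()}
        table = {el: [(DEFAULT_ISOTOPES[el][0][0], 1.0)] for el in DEFAULT_ISOTOPES}
        corr = build_correction(parse_formula("C5H10N2O3"), table)
        assert np.allclose(corr.matrix, np.eye(18))

    def test_one_carbon_binomial_column(self):
        # formaldehyde-like single carbon: observed M0 column is (1-p, p)
        corr = build_correction(parse_formula("CH2O"))
        col = corr.matrix[:, 0]
        assert col[0] == pytest.approx(0.9893, abs=1e-12)
        assert col[1] == pytest.approx(0.0107, abs=1e-12)

    def test_kronecker_structure_matches_atom_enumeration(self):
        """Resolved C and N axes are independent: the matrix equals a direct
        multinomial enumeration over every C and N atom."""
        f = parse_formula("C3H5N2O")  # small enough for exhaustive enumeration
        corr = build_correction(f)
        p13 = DEFAULT_ISOTOPES["C"][1][1]
        p15 = DEFAULT_ISOTOPES["N"][1][1]
        nC, nN = 3, 2
        brute = np.zeros(((nC + 1) * (nN + 1), (nC + 1) * (nN + 1)))
        for tc in range(nC + 1):          # true 13C count
            for tn in range(nN + 1):      # true 15N count
                col = tc * (nN + 1) + tn
                # enumerate isotope choice of each unlabeled atom
                for cbits in itertools.product([0, 1], repeat=nC - tc):
                    for nbits in itertools.product([0, 1], repeat=nN - tn):
                        pc = np.prod([p13 if b else 1 - p13 for b in cbits]) if cbits else 1.0
                        pn = np.prod([p15 if b else 1 - p15 for b in nbits]) if nbits else 1.0
                        oc, on = tc + sum(cbits), tn + sum(nbits)
                        brute[oc * (nN + 1) + on, col] += pc * pn
        assert np.allclose(corr.matrix, brute, atol=1e-12)

    def test_round_trip_identity_matrix(self):
        corr = build_correction(parse_formula("CH2O"))
        eye = build_correction(
            parse_formula("CH2O"),
            {el: [(DEFAULT_ISOTOPES[el][0][0], 1.0)] for el in DEFAULT_ISOTOPES},
        )
        raw = MIDGrid("x", np.array([[0.4], [0.6]]))
        out = correct_mid(raw, eye)
        assert np.allclose(out.mid.f, raw.f)

    def test_round_trip_one_carbon(self):
        corr = build_correction(parse_formula("CH2O"))
        observed = MIDGrid("x", np.array([[0.9893], [0.0107]]))
        out = correct_mid(observed, corr)
        assert out.mid.f[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert out.mid.f[1, 0] == pytest.approx(0.0, abs=1e-8)

    def test_round_trip_random_grids(self, rng):
        f = parse_formula("C5H10N2O3")
        corr = build_correction(f)
        for _ in range(20):
            true = rng.random((6, 3))
            true /= true.sum()
            observed = forward_convolve(MIDGrid("gln", true), corr).normalized()
            out = correct_mid(observed, corr)
            assert np.abs(out.mid.f - true).max() < 1e-8

    def test_purity_bounds(self):
        with pytest.raises(ValueError):
            build_correction(parse_formula("CH2O"), purity={"C": 0.0})


class TestPercentLabeled:
    def test_fully_labeled_and_unlabeled(self):
        f = np.zeros((6, 3))
        f[5, 2] = 1.0
        mid = MIDGrid("gln", f)
        assert percent_labeled(mid, "C", 5) == pytest.approx(1.0)
        assert percent_labeled(mid, "N", 2) == pytest.approx(1.0)
        g = np.zeros((6, 3))
        g[0, 0] = 1.0
        assert percent_labeled(MIDGrid("gln", g), "C", 5) == 0.0

    def test_imp_two_of_four_nitrogens(self):
        # half the molecules carry 2 of 4 labeled N -> atom fraction 0.25
        f = np.zeros((11, 5))
        f[0, 0] = 0.5
        f[0, 2] = 0.5
        assert percent_labeled(MIDGrid("IMP", f), "N", 4) == pytest.approx(0.25)

    def test_molecule_fraction_differs_from_atom_fraction(self):
        f = np.zeros((11, 5))
        f[0, 0] = 0.5
        f[0, 2] = 0.5
        mid = MIDGrid("IMP", f)
        assert molecule_labeled_fraction(mid, "N") == pytest.approx(0.5)

    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        alpha=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_renormalization_invariance_and_mixture_linearity(self, scale, alpha, seed):
        r = np.random.default_rng(seed)
        a = r.random((6, 3))
        b = r.random((6, 3))
        a /= a.sum()
        b /= b.sum()
        pa = percent_labeled(MIDGrid("m", a), "C", 5)
        assert percent_labeled(MIDGrid("m", a * scale), "C", 5) == pytest.approx(pa)
        mix = alpha * a + (1 - alpha) * b
        pb = percent_labeled(MIDGrid("m", b), "C", 5)
        assert percent_labeled(MIDGrid("m", mix), "C", 5) == pytest.approx(
            alpha * pa + (1 - alpha) * pb, abs=1e-12
        )

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            percent_labeled(MIDGrid("m", np.ones((2, 2)) / 4), "C", 0)


class TestIsotopeTableValidation:
    def test_bad_abundance_sum(self):
        with pytest.raises(ValueError):
            validate_isotope_table({"C": [(12.0, 0.5), (13.0033, 0.4)]})

    def test_nonincreasing_masses(self):
        with pytest.raises(ValueError):
            validate_isotope_table({"C": [(13.0033, 0.5), (12.0, 0.5)]})
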