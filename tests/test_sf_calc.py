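import cmath
import math

import numpy as np
import pytest

from trxdiff.model_io import Atom, AtomicModel, UnitCell
from trxdiff.sf_calc import (
    CROMER_MANN,
    ReflectionError,
    ReflectionSet,
    calc_structure_factors,
    common_indices,
    form_factor,
    generate_hkl,
    read_reflections,
    write_reflections,
)

ELECTRON_COUNTS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "FE": 26}


class TestGenerateHkl:
    def test_matches_brute_force_enumeration(self, cubic_cell):
        # 4.1 A keeps the resolution limit away from exact index-sphere
        # boundaries, where float rounding would make the set comparison moot
        d_min = 4.1
        got = {tuple(row) for row in generate_hkl(cubic_cell, d_min)}
        # independent enumeration over an amply large index cube
        expected = set()
        for h in range(-8, 9):
            for k in range(-8, 9):
                for l in range(-8, 9):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    hemi = h > 0 or (h == 0 and k > 0) or (h == 0 and k == 0 and l > 0)
                    d = 20.0 / math.sqrt(h * h + k * k + l * l)
                    if hemi and d >= d_min:
                        expected.add((h, k, l))
        assert got == expected

    def test_no_friedel_mates(self, cubic_cell):
        hkl = generate_hkl(cubic_cell, 3.0)
        keys = {tuple(row) for row in hkl}
        assert not any(tuple(-np.array(k)) in keys for k in keys)

    def test_d_max_filter(self, cubic_cell):
        hkl = generate_hkl(cubic_cell, 4.0, d_max=10.0)
        d = cubic_cell.d_spacing(hkl)
        assert np.all((d >= 4.0) & (d <= 10.0))

    def test_deterministic_order(self, cubic_cell):
        a = generate_hkl(cubic_cell, 3.0)
        b = generate_hkl(cubic_cell, 3.0)
        np.testing.assert_array_equal(a, b)

    def test_invalid_range(self, cubic_cell):
        with pytest.raises(ReflectionError):
            generate_hkl(cubic_cell, -1.0)


class TestFormFactor:
    @pytest.mark.parametrize("element,z", sorted(ELECTRON_COUNTS.items()))
    def test_f_at_zero_is_electron_count(self, element, z):
        assert form_factor(element, 0.0) == pytest.approx(z, abs=0.1)

    def test_monotone_decreasing(self):
        s = np.linspace(0.0, 0.6, 50)
        f = form_factor("C", s)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element(self):
        with pytest.raises(ReflectionError):
            form_factor("XE", 0.1)

    def test_negative_s(self):
        with pytest.raises(ReflectionError):
            form_factor("C", -0.1)


def _independent_direct_sum(model, hkls):
    """Plain-Python reference structure-factor sum (no shared vectorized code)."""
    results = []
    frac = model.fractional_positions()
    for hkl in hkls:
        h, k, l = (int(v) for v in hkl)
        d = float(model.cell.d_spacing(np.array([[h, k, l]]))[0])
        s = 0.5 / d
        total = 0.0 + 0.0j
        for atom, (x, y, z) in zip(model.atoms, frac):
            a_coef, b_coef, c_coef = CROMER_MANN[atom.element.upper()]
            f = c_coef + sum(ai * math.exp(-bi * s * s) for ai, bi in zip(a_coef, b_coef))
            dw = math.exp(-atom.b_factor * s * s)
            total += atom.occupancy * f * dw * cmath.exp(2j * math.pi * (h * x + k * y + l * z))
        results.append(total)
    return np.array(results)


class TestCalcStructureFactors:
    def test_matches_independent_direct_sum(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 2.5)
        fc = calc_structure_factors(three_atom_model, hkl)
        ref = _independent_direct_sum(three_atom_model, hkl)
        np.testing.assert_allclose(fc.complex_values(), ref, rtol=1e-8, atol=1e-10)

    def test_single_atom_at_origin(self, cubic_cell):
        model = AtomicModel(
            atoms=[Atom("O", "O1", "HOH", 1, "A", (0.0, 0.0, 0.0), b_factor=20.0)], cell=cubic_cell
        )
        hkl = np.array([[1, 0, 0], [2, 2, 0]])
        fc = calc_structure_factors(model, hkl)
        s = 0.5 / cubic_cell.d_spacing(hkl)
        expected = form_factor("O", s) * np.exp(-20.0 * s**2)
        np.testing.assert_allclose(fc.amplitude, expected, rtol=1e-12)
        np.testing.assert_allclose(fc.phase, 0.0, atol=1e-9)

    def test_translation_leaves_amplitudes_invariant(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 3.0)
        fc = calc_structure_factors(three_atom_model, hkl)
        shifted = three_atom_model.with_positions(three_atom_model.positions() + [1.7, -2.3, 0.9])
        fc2 = calc_structure_factors(shifted, hkl)
        np.testing.assert_allclose(fc2.amplitude, fc.amplitude, rtol=1e-9)

    def test_friedel_symmetry(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 3.0)
        fc = calc_structure_factors(three_atom_model, hkl)
        fc_neg = calc_structure_factors(three_atom_model, -hkl)
        np.testing.assert_allclose(fc_neg.amplitude, fc.amplitude, rtol=1e-9)
        np.testing.assert_allclose(
            fc_neg.complex_values(), np.conj(fc.complex_values()), rtol=1e-9, atol=1e-9
        )

    def test_b_increase_damps_high_resolution(self, cubic_cell):
        hot = AtomicModel(
            atoms=[Atom("C", "C1", "LIG", 1, "A", (3.0, 4.0, 5.0), b_factor=30.0)], cell=cubic_cell
        )
        cold = AtomicModel(
            atoms=[Atom("C", "C1", "LIG", 1, "A", (3.0, 4.0, 5.0), b_factor=5.0)], cell=cubic_cell
        )
        hkl = generate_hkl(cubic_cell, 2.0)
        ratio = calc_structure_factors(hot, hkl).amplitude / calc_structure_factors(cold, hkl).amplitude
        s2 = (0.5 / cubic_cell.d_spacing(hkl)) ** 2
        np.testing.assert_allclose(ratio, np.exp(-25.0 * s2), rtol=1e-9)

    def test_p212121_equals_manual_expansion(self, cubic_cell):
        atoms = [
            Atom("C", "C1", "LIG", 1, "A", (2.5, 6.1, 9.9), b_factor=11.0),
            Atom("N", "N1", "LIG", 1, "A", (4.4, 3.2, 7.7), b_factor=9.0),
        ]
        sym = AtomicModel(atoms=atoms, cell=cubic_cell, space_group="P 21 21 21")
        # manual P212121 expansion: (x,y,z), (1/2-x,-y,1/2+z), (-x,1/2+y,1/2-z), (1/2+x,1/2-y,-z)
        frac = sym.fractional_positions()
        ops = [
            lambda p: p,
            lambda p: np.array([0.5 - p[0], -p[1], 0.5 + p[2]]),
            lambda p: np.array([-p[0], 0.5 + p[1], 0.5 - p[2]]),
            lambda p: np.array([0.5 + p[0], 0.5 - p[1], -p[2]]),
        ]
        expanded_atoms = []
        for op in ops:
            for atom, p in zip(atoms, frac):
                cart = (op(p) @ cubic_cell.orthogonalization_matrix.T)
                expanded_atoms.append(atom.moved_to(cart))
        p1 = AtomicModel(atoms=expanded_atoms, cell=cubic_cell, space_group="P 1")
        hkl = generate_hkl(cubic_cell, 2.5)
        fa = calc_structure_factors(sym, hkl)
        fb = calc_structure_factors(p1, hkl)
        np.testing.assert_allclose(fa.complex_values(), fb.complex_values(), rtol=1e-8, atol=1e-8)

    def test_unsupported_space_group(self, three_atom_model):
        bad = AtomicModel(atoms=three_atom_model.atoms, cell=three_atom_model.cell, space_group="C 2")
        with pytest.raises(ReflectionError):
            calc_structure_factors(bad, np.array([[1, 0, 0]]))


class TestReflectionSet:
    def test_duplicate_indices_rejected(self, cubic_cell):
        with pytest.raises(ReflectionError):
            ReflectionSet(hkl=[[1, 0, 0], [1, 0, 0]], amplitude=[1.0, 2.0], cell=cubic_cell)

    def test_length_mismatch_rejected(self, cubic_cell):
        with pytest.raises(ReflectionError):
            ReflectionSet(hkl=[[1, 0, 0]], amplitude=[1.0, 2.0], cell=cubic_cell)

    def test_complex_values_need_phases(self, cubic_cell):
        rset = ReflectionSet(hkl=[[1, 0, 0]], amplitude=[1.0], cell=cubic_cell)
        with pytest.raises(ReflectionError):
            rset.complex_values()

    def test_common_indices(self, cubic_cell):
        a = ReflectionSet(hkl=[[1, 0, 0], [2, 0, 0], [3, 0, 0]], amplitude=[1, 2, 3], cell=cubic_cell)
        b = ReflectionSet(hkl=[[3, 0, 0], [1, 0, 0], [5, 0, 0]], amplitude=[9, 8, 7], cell=cubic_cell)
        ia, ib = common_indices(a, b)
        np.testing.assert_array_equal(a.hkl[ia], b.hkl[ib])
        assert {tuple(r) for r in a.hkl[ia]} == {(1, 0, 0), (3, 0, 0)}

    def test_tsv_roundtrip_full_columns(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 3.0)
        fc = calc_structure_factors(three_atom_model, hkl)
        fc.sigma = 0.05 * fc.amplitude
        fc.weight = np.full(len(fc), 0.5)
        back = read_reflections(write_reflections(fc), three_atom_model.cell, label=fc.label)
        np.testing.assert_array_equal(back.hkl, fc.hkl)
        np.testing.assert_allclose(back.amplitude, fc.amplitude, rtol=1e-6)
        np.testing.assert_allclose(back.phase, fc.phase, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(back.sigma, fc.sigma, rtol=1e-6)
        np.testing.assert_allclose(back.weight, fc.weight, rtol=1e-6)

    def test_tsv_roundtrip_absent_columns(self, cubic_cell):
        rset = ReflectionSet(hkl=[[1, 0, 0], [0, 2, 1]], amplitude=[3.5, -1.25], cell=cubic_cell)
        back = read_reflections(write_reflections(rset), cubic_cell)
        assert back.sigma is None and back.phase is None and back.weight is None
        np.testing.assert_allclose(back.amplitude, rset.amplitude)

    def test_read_missing_columns_errors(self, cubic_cell):
        with pytest.raises(ReflectionError):
            read_reflections("h\tk\n1\t2\n", cubic_cell)
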