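import math

import gemmi
import numpy as np
import pytest

from trxdiff.maps import (
    Map3D,
    MapError,
    default_grid,
    diff_diff_map,
    find_peaks,
    local_pcc,
    masked_pcc,
    sigma_scale,
    synthesize_map,
    write_ccp4,
)
from trxdiff.model_io import Atom, AtomicModel, UnitCell
from trxdiff.sf_calc import ReflectionSet, calc_structure_factors, generate_hkl


def _low_res_coeffs(cell, n_coeffs=20, seed=11):
    """Random phased coefficients safe for an 8x8x8 grid on a 20 A cell."""
    hkls = []
    for h in range(0, 4):
        for k in range(-3, 4):
            for l in range(-3, 4):
                hemi = h > 0 or (h == 0 and k > 0) or (h == 0 and k == 0 and l > 0)
                if hemi and 0 < h * h + k * k + l * l <= 16:
                    hkls.append((h, k, l))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(hkls), size=n_coeffs, replace=False)
    hkl = np.array([hkls[i] for i in pick])
    return ReflectionSet(
        hkl=hkl,
        amplitude=rng.uniform(0.5, 5.0, n_coeffs),
        cell=cell,
        phase=rng.uniform(-180.0, 180.0, n_coeffs),
        label="test_coeffs",
    )


class TestSynthesizeMap:
    def test_matches_double_loop_oracle(self, cubic_cell):
        coeffs = _low_res_coeffs(cubic_cell)
        grid = (8, 8, 8)
        fmap = synthesize_map(coeffs, grid)
        # direct double-loop summation: rho(x) = (2/V) sum_h Re(F_h exp(-2 pi i h.x))
        F = coeffs.complex_values()
        expected = np.zeros(grid)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    x = np.array([i / 8, j / 8, k / 8])
                    phases = np.exp(-2j * np.pi * (coeffs.hkl @ x))
                    expected[i, j, k] = 2.0 * np.real(np.sum(F * phases)) / cubic_cell.volume
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(fmap.values - expected)) / scale <= 1e-6

    def test_zero_mean(self, cubic_cell):
        fmap = synthesize_map(_low_res_coeffs(cubic_cell), (8, 8, 8))
        assert abs(np.mean(fmap.values)) < 1e-12 * np.max(np.abs(fmap.values))

    def test_parseval(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 2.0)
        fc = calc_structure_factors(three_atom_model, hkl)
        grid = default_grid(three_atom_model.cell, 2.0)
        fmap = synthesize_map(fc, grid)
        var = float(np.mean(fmap.values**2))
        expected = 2.0 * float(np.sum(fc.amplitude**2)) / three_atom_model.cell.volume**2
        assert var == pytest.approx(expected, rel=1e-9)

    def test_requires_phases(self, cubic_cell):
        rset = ReflectionSet(hkl=[[1, 0, 0]], amplitude=[1.0], cell=cubic_cell)
        with pytest.raises(MapError):
            synthesize_map(rset, (8, 8, 8))

    def test_rejects_too_coarse_grid(self, three_atom_model):
        hkl = generate_hkl(three_atom_model.cell, 2.0)
        fc = calc_structure_factors(three_atom_model, hkl)
        with pytest.raises(MapError):
            synthesize_map(fc, (8, 8, 8))  # spacing 2.5 A >> d_min/2 = 1 A

    def test_signed_amplitude_is_phase_flip(self, cubic_cell):
        pos = ReflectionSet(hkl=[[1, 1, 0]], amplitude=[2.0], cell=cubic_cell, phase=[30.0])
        neg = ReflectionSet(hkl=[[1, 1, 0]], amplitude=[-2.0], cell=cubic_cell, phase=[30.0])
        ma = synthesize_map(pos, (8, 8, 8))
        mb = synthesize_map(neg, (8, 8, 8))
        np.testing.assert_allclose(mb.values, -ma.values, atol=1e-15)


class TestSigmaScale:
    def test_unit_rms_and_idempotence(self, cubic_cell):
        fmap = synthesize_map(_low_res_coeffs(cubic_cell), (8, 8, 8))
        scaled = sigma_scale(fmap)
        assert scaled.rms() == pytest.approx(1.0, rel=1e-12)
        assert scaled.scale_tag == "sigma"
        twice = sigma_scale(scaled)
        np.testing.assert_allclose(twice.values, scaled.values, rtol=1e-12)

    def test_constant_map_rejected(self, cubic_cell):
        with pytest.raises(MapError):
            sigma_scale(Map3D(values=np.ones((8, 8, 8)), cell=cubic_cell))


class TestDefaultGrid:
    def test_spacing_and_parity(self, cubic_cell):
        grid = default_grid(cubic_cell, 1.5)
        for n, length in zip(grid, (20.0, 20.0, 20.0)):
            assert n % 2 == 0
            assert length / n <= 1.5 / 3.0 + 1e-12


class TestLocalPcc:
    @pytest.fixture
    def two_maps(self, cubic_cell):
        a = synthesize_map(_low_res_coeffs(cubic_cell, seed=1), (8, 8, 8))
        b = synthesize_map(_low_res_coeffs(cubic_cell, seed=2), (8, 8, 8))
        return a, b

    def test_symmetry(self, two_maps):
        a, b = two_maps
        center = np.array([10.0, 10.0, 10.0])
        assert local_pcc(a, b, center, 6.0) == pytest.approx(local_pcc(b, a, center, 6.0), rel=1e-12)

    def test_self_correlation_is_one(self, two_maps):
        a, _ = two_maps
        assert local_pcc(a, a, np.array([5.0, 5.0, 5.0]), 6.0) == pytest.approx(1.0)

    def test_linear_transform_invariance(self, two_maps):
        a, b = two_maps
        center = np.array([10.0, 10.0, 10.0])
        b2 = b.copy_with(3.0 * b.values + 7.0)
        assert local_pcc(a, b2, center, 6.0) == pytest.approx(local_pcc(a, b, center, 6.0), rel=1e-10)

    def test_grid_mismatch(self, two_maps, cubic_cell):
        a, _ = two_maps
        other = Map3D(values=np.zeros((10, 10, 10)), cell=cubic_cell)
        with pytest.raises(MapError):
            masked_pcc(a, other, np.zeros((1, 3)), 5.0)

    def test_sphere_too_small(self, two_maps):
        a, b = two_maps
        with pytest.raises(MapError):
            local_pcc(a, b, np.array([5.0, 5.0, 5.0]), 0.5)


class TestDiffDiffMap:
    def test_hand_oracle(self, cubic_cell):
        obs_v = np.zeros((8, 8, 8))
        calc_v = np.zeros((8, 8, 8))
        obs_v[1, 1, 1], obs_v[2, 2, 2] = 4.0, -2.0
        calc_v[1, 1, 1], calc_v[2, 2, 2] = 8.0, -6.0
        obs = Map3D(values=obs_v, cell=cubic_cell)
        calc = Map3D(values=calc_v, cell=cubic_cell)
        dd = diff_diff_map(obs, calc)
        # affine fit: a = (8 - (-6)) / (4 - (-2)) = 7/3, b = 8 - a*4
        a, b = 14.0 / 6.0, 8.0 - (14.0 / 6.0) * 4.0
        np.testing.assert_allclose(dd.values, a * obs_v + b - calc_v, rtol=1e-12)
        # matched extremes cancel exactly
        assert dd.values[1, 1, 1] == pytest.approx(0.0, abs=1e-12)
        assert dd.values[2, 2, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self, cubic_cell):
        flat = Map3D(values=np.ones((8, 8, 8)), cell=cubic_cell)
        bumpy = Map3D(values=np.arange(512, dtype=float).reshape(8, 8, 8), cell=cubic_cell)
        with pytest.raises(MapError):
            diff_diff_map(flat, bumpy)


def _sigma_map(cell, spikes):
    v = np.zeros((20, 20, 20))
    for (i, j, k), h in spikes.items():
        v[i, j, k] = h
    return Map3D(values=v, cell=cell, scale_tag="sigma", label="planted")


class TestFindPeaks:
    def test_planted_peaks_found_and_sorted(self, cubic_cell):
        # 20-grid on a 20 A cell: voxel (i,j,k) sits at (i, j, k) A
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (12, 3, 8): -7.0, (15, 15, 15): 5.0})
        peaks = find_peaks(fmap, threshold=3.0)
        assert [p.height for p in peaks] == [10.0, -7.0, 5.0]
        np.testing.assert_allclose(peaks.peaks[0].position, (5.0, 5.0, 5.0), atol=1e-9)
        np.testing.assert_allclose(peaks.peaks[1].position, (12.0, 3.0, 8.0), atol=1e-9)

    def test_threshold_excludes_weak(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (15, 15, 15): 2.0})
        assert len(find_peaks(fmap, threshold=3.0)) == 1

    def test_same_sign_suppression(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (5, 5, 6): 8.0})  # 1 A apart
        peaks = find_peaks(fmap, threshold=3.0, min_separation=2.0)
        assert [p.height for p in peaks] == [10.0]

    def test_opposite_signs_not_suppressed(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (5, 5, 6): -8.0})
        peaks = find_peaks(fmap, threshold=3.0, min_separation=2.0)
        assert sorted(p.height for p in peaks) == [-8.0, 10.0]

    def test_negated_map_flips_peaks(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (12, 3, 8): -7.0})
        fwd = find_peaks(fmap, threshold=3.0)
        rev = find_peaks(fmap.copy_with(-fmap.values), threshold=3.0)
        assert sorted(p.height for p in rev) == sorted(-p.height for p in fwd)
        assert {p.position for p in rev} == {p.position for p in fwd}

    def test_attribution(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0, (15, 15, 15): 5.0})
        model = AtomicModel(
            atoms=[t for t in [Atom("O", "O", "HOH", 1, "A", (5.5, 5.0, 5.0))]], cell=cubic_cell
        )
        peaks = find_peaks(fmap, threshold=3.0, model=model)
        assert peaks.peaks[0].nearest_atom == "A/HOH 1/O"
        assert peaks.peaks[0].nearest_distance == pytest.approx(0.5, abs=1e-9)
        assert peaks.peaks[1].nearest_atom is None  # beyond the attribution cutoff

    def test_periodic_wraparound_distance(self, cubic_cell):
        # peaks at opposite cell edges are 2 A apart through the boundary
        fmap = _sigma_map(cubic_cell, {(0, 5, 5): 10.0, (19, 5, 5): 8.0})
        peaks = find_peaks(fmap, threshold=3.0, min_separation=2.5)
        assert [p.height for p in peaks] == [10.0]

    def test_requires_sigma_scale(self, cubic_cell):
        fmap = Map3D(values=np.zeros((8, 8, 8)), cell=cubic_cell)  # absolute tag
        with pytest.raises(MapError):
            find_peaks(fmap, threshold=3.0)

    def test_table_format(self, cubic_cell):
        fmap = _sigma_map(cubic_cell, {(5, 5, 5): 10.0})
        table = find_peaks(fmap, threshold=3.0).to_table()
        lines = table.strip().splitlines()
        assert lines[0].startswith("rank\tsign\theight_sigma")
        assert lines[1].split("\t")[1] == "+"


class TestWriteCcp4:
    def test_roundtrip_through_gemmi(self, cubic_cell, tmp_path):
        fmap = synthesize_map(_low_res_coeffs(cubic_cell), (8, 8, 8))
        path = tmp_path / "map.ccp4"
        write_ccp4(fmap, str(path))
        m = gemmi.read_ccp4_map(str(path))
        arr = np.array(m.grid, copy=False)
        np.testing.assert_allclose(arr, fmap.values, rtol=1e-6, atol=1e-9)
        assert m.grid.unit_cell.a == pytest.approx(20.0, abs=1e-4)
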