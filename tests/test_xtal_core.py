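import numpy as np
import pytest

from trsfx.xtal_core import (AtomModel, CROMER_MANN, InsufficientOverlapError,
                             MissingPhaseError, ReflectionSet, UnitCell,
                             UnknownElementError, calc_structure_factors,
                             ded_map, delta_f, difference_amplitudes,
                             scale_to_reference, synthesize_map, unique_hkl)


def brute_force_sf(model, hkl):
    """Independent direct summation, scalar python loops."""
    out = []
    frac = model.frac()
    for h in hkl:
        d = float(model.cell.d_spacing(np.array([h]))[0])
        s2 = 1.0 / (4 * d * d)
        f = 0j
        for j, el in enumerate(model.elements):
            a, b, c = CROMER_MANN[el]
            fj = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
            dw = np.exp(-model.b[j] * s2)
            f += model.occ[j] * fj * dw * np.exp(2j * np.pi * np.dot(h, frac[j]))
        out.append(f)
    return np.array(out)


class TestUnitCell:
    def test_orthorhombic_volume(self):
        assert UnitCell(2, 3, 4).volume == pytest.approx(24.0)

    def test_triclinic_roundtrip(self):
        cell = UnitCell(10, 11, 12, 80, 95, 103)
        xyz = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert np.allclose(cell.orthogonalize(cell.fractionalize(xyz)), xyz)

    def test_d_spacing_orthorhombic(self):
        cell = UnitCell(10, 20, 30)
        assert cell.d_spacing(np.array([[2, 0, 0]]))[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("bad", [dict(a=-1, b=1, c=1),
                                     dict(a=1, b=1, c=1, alpha=200)])
    def test_invalid_cells(self, bad):
        kw = dict(a=1.0, b=1.0, c=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            UnitCell(**kw)


class TestCalcStructureFactors:
    def test_origin_atom_phases_zero(self, cell):
        model = AtomModel(elements=["C"], res_ids=np.array([1]),
                          res_names=["ALA"], atom_names=["CA"],
                          xyz=np.zeros((1, 3)), occ=np.ones(1),
                          b=np.zeros(1), cell=cell)
        sf = calc_structure_factors(model, 3.0)
        assert np.allclose(sf.phase, 0.0, atol=1e-9)
        assert np.all(sf.amp > 0)

    def test_shift_theorem(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.5)
        shifted = five_atom_model.copy()
        t = np.array([1.3, -0.7, 2.1])
        shifted.xyz = shifted.xyz + t
        sf2 = calc_structure_factors(shifted, 2.5)
        assert np.allclose(sf2.amp, sf.amp, rtol=1e-10)
        t_frac = five_atom_model.cell.fractionalize(t)
        expected = sf.phase + 360.0 * (sf.hkl @ t_frac)
        dphi = (sf2.phase - expected + 180.0) % 360.0 - 180.0
        assert np.allclose(dphi, 0.0, atol=1e-8)

    def test_against_brute_force(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        ref = brute_force_sf(five_atom_model, sf.hkl)
        assert np.allclose(sf.amp, np.abs(ref), rtol=1e-6)
        dphi = (sf.phase - np.degrees(np.angle(ref)) + 180.0) % 360.0 - 180.0
        assert np.allclose(dphi, 0.0, atol=1e-6)

    def test_friedel_symmetry(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.5)
        ref = brute_force_sf(five_atom_model, -sf.hkl)
        assert np.allclose(np.abs(ref), sf.amp, rtol=1e-10)
        dphi = (np.degrees(np.angle(ref)) + sf.phase + 180.0) % 360.0 - 180.0
        assert np.allclose(dphi, 0.0, atol=1e-8)

    def test_unknown_element(self, five_atom_model):
        bad = five_atom_model.copy()
        bad.elements[2] = "Xx"
        with pytest.raises(UnknownElementError, match="Xx"):
            calc_structure_factors(bad, 2.5)

    def test_d_min_larger_than_cell(self, five_atom_model):
        with pytest.raises(ValueError, match="no reflections"):
            calc_structure_factors(five_atom_model, 50.0)

    def test_resolution_limit_respected(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        assert sf.d().min() >= 2.0 - 1e-9

    def test_unique_hemisphere(self, cell):
        hkl = unique_hkl(cell, 3.0)
        keys = {tuple(h) for h in hkl}
        assert not any(tuple(-h) in keys for h in hkl)


class TestScaleToReference:
    def test_identity(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        obs = ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=0.01 * sf.amp,
                            cell=sf.cell, d_min=sf.d_min, role="observed-dark")
        scaled = scale_to_reference(obs, obs)
        assert scaled.meta["scale_k"] == pytest.approx(1.0, abs=1e-8)
        assert scaled.meta["scale_b_rel"] == pytest.approx(0.0, abs=1e-8)

    def test_pure_scale(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        ref = ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=0.01 * sf.amp,
                            cell=sf.cell, d_min=sf.d_min, role="observed-dark")
        moving = ref.subset(np.arange(len(ref)), amp=2.0 * ref.amp)
        scaled = scale_to_reference(moving, ref)
        assert scaled.meta["scale_k"] == pytest.approx(0.5, abs=1e-8)
        assert scaled.meta["scale_b_rel"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(scaled.amp, ref.amp)

    def test_recover_known_k_and_b(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        ref = ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=0.01 * sf.amp,
                            cell=sf.cell, d_min=sf.d_min, role="observed-dark")
        k_true, b_true = 0.7, 12.0
        factor = k_true * np.exp(-b_true / (4 * ref.d() ** 2))
        moving = ref.subset(np.arange(len(ref)), amp=ref.amp / factor,
                            sigma=ref.sigma / factor)
        scaled = scale_to_reference(moving, ref)
        assert scaled.meta["scale_k"] == pytest.approx(k_true, rel=0.01)
        assert scaled.meta["scale_b_rel"] == pytest.approx(b_true, abs=0.5)

    def test_insufficient_overlap(self, five_atom_model, cell):
        sf = calc_structure_factors(five_atom_model, 2.0)
        small = sf.subset(np.arange(5))
        with pytest.raises(InsufficientOverlapError):
            scale_to_reference(small, small)


class TestDifferenceAmplitudes:
    @staticmethod
    def _observed(sf, sigma_frac=0.01):
        return ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=sigma_frac * sf.amp,
                             cell=sf.cell, d_min=sf.d_min, role="observed-dark")

    def test_identical_parents_zero(self, five_atom_model):
        obs = self._observed(calc_structure_factors(five_atom_model, 2.0))
        diff = difference_amplitudes(obs, obs, snr_min=3, d_low=10.0)
        assert np.allclose(delta_f(diff), 0.0)
        expected = np.sum(obs.d() < 10.0)
        assert len(diff) == expected

    def test_low_resolution_cut(self, toy_model):
        sf = calc_structure_factors(toy_model, 2.0)
        obs = self._observed(sf)
        d = obs.d()
        assert d.max() > 10.0  # the toy cell has reflections beyond 10 A
        diff = difference_amplitudes(obs, obs, snr_min=0, d_low=10.0)
        assert diff.d().max() < 10.0

    def test_snr_filter_matches_enumeration(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        rng = np.random.default_rng(3)
        sig_l = sf.amp * rng.uniform(0.1, 0.6, len(sf))
        sig_d = sf.amp * rng.uniform(0.1, 0.6, len(sf))
        light = ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=sig_l,
                              cell=sf.cell, d_min=sf.d_min, role="observed-light")
        dark = ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=sig_d,
                             cell=sf.cell, d_min=sf.d_min, role="observed-dark")
        diff = difference_amplitudes(light, dark, snr_min=3.0, d_low=10.0)
        # brute-force enumeration
        count = 0
        for i in range(len(sf)):
            d = sf.d()[i]
            if d >= 10.0 or d < sf.d_min:
                continue
            if sf.amp[i] / sig_l[i] > 3.0 and sf.amp[i] / sig_d[i] > 3.0:
                count += 1
        assert len(diff) == count

    def test_empty_result_warns(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.0)
        obs = self._observed(sf, sigma_frac=10.0)  # SNR 0.1 everywhere
        with pytest.warns(UserWarning, match="no reflections"):
            diff = difference_amplitudes(obs, obs, snr_min=3.0)
        assert len(diff) == 0


class TestSynthesizeMap:
    def test_single_reflection_cosine(self, cell):
        rs = ReflectionSet(hkl=[[1, 0, 0]], amp=[5.0], sigma=[0.0], cell=cell,
                           d_min=5.0, phase=[0.0])
        dmap = synthesize_map(rs, grid=(8, 8, 8))
        peak = 2 * 5.0 / cell.volume
        assert dmap.values.max() == pytest.approx(peak, rel=1e-10)
        assert dmap.values.min() == pytest.approx(-peak, rel=1e-10)
        assert dmap.values[0, 0, 0] == pytest.approx(peak)

    def test_zero_amplitudes(self, cell):
        rs = ReflectionSet(hkl=[[1, 0, 0], [0, 2, 1]], amp=[0.0, 0.0],
                           sigma=[0.0, 0.0], cell=cell, d_min=3.0,
                           phase=[10.0, 20.0])
        dmap = synthesize_map(rs, grid=(8, 8, 8))
        assert np.all(dmap.values == 0)
        assert dmap.map_sigma == 0.0

    def test_against_direct_summation(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 4.0)
        dmap = synthesize_map(sf, grid=(8, 8, 8))
        f = sf.amp * np.exp(1j * np.radians(sf.phase))
        v = five_atom_model.cell.volume
        for idx in [(0, 0, 0), (1, 2, 3), (7, 5, 2), (4, 4, 4)]:
            x = np.array(idx) / 8.0
            rho = np.sum(2 * np.real(f * np.exp(-2j * np.pi * (sf.hkl @ x)))) / v
            assert dmap.values[idx] == pytest.approx(rho, abs=1e-8)

    def test_zero_mean(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 3.0)
        dmap = synthesize_map(sf, grid=(10, 10, 10))
        assert abs(dmap.values.mean()) < 1e-12

    def test_parseval(self, five_atom_model):
        sf = calc_structure_factors(five_atom_model, 2.5)
        dmap = synthesize_map(sf, grid=(12, 12, 12))
        v = five_atom_model.cell.volume
        lhs = 2 * np.sum(sf.amp**2)  # full Friedel sphere
        rhs = v**2 * np.mean(dmap.values**2)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_missing_phases(self, cell):
        rs = ReflectionSet(hkl=[[1, 0, 0]], amp=[1.0], sigma=[0.0], cell=cell,
                           d_min=5.0, phase=None)
        with pytest.raises(MissingPhaseError):
            synthesize_map(rs, grid=(8, 8, 8))

    def test_nyquist_guard(self, cell):
        rs = ReflectionSet(hkl=[[4, 0, 0]], amp=[1.0], sigma=[0.0], cell=cell,
                           d_min=2.0, phase=[0.0])
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_map(rs, grid=(8, 8, 8))


class TestDedMap:
    @staticmethod
    def _observed(sf, role):
        return ReflectionSet(hkl=sf.hkl, amp=sf.amp, sigma=0.01 * sf.amp,
                             cell=sf.cell, d_min=sf.d_min, role=role)

    def test_light_equals_dark_zero_map(self, toy_model):
        sf = calc_structure_factors(toy_model, 2.0)
        obs = self._observed(sf, "observed-dark")
        dmap = ded_map(obs, obs, toy_model, scale=False)
        assert dmap.map_sigma == pytest.approx(0.0, abs=1e-12)
        assert dmap.provenance == "observed-DED"

    def test_antisymmetry(self, toy_model, toy_light):
        from trsfx.synthetic import simulate_dataset
        dark_obs, light_obs = simulate_dataset(toy_model, toy_light, 0.5,
                                               noise_frac=0.0, seed=0, d_min=2.0)
        a = ded_map(light_obs, dark_obs, toy_model, scale=False)
        b = ded_map(dark_obs, light_obs, toy_model, scale=False)
        assert np.allclose(a.values, -b.values, atol=1e-10)

    def test_displaced_atom_peaks(self, toy_model):
        displaced = toy_model.copy()
        i = displaced.index_of((12, "O"))  # a water, 1 A shift
        old_pos = displaced.xyz[i].copy()
        displaced.xyz[i] = old_pos + np.array([1.0, 0.0, 0.0])
        from trsfx.synthetic import simulate_dataset
        dark_obs, light_obs = simulate_dataset(toy_model, displaced, 1.0,
                                               noise_frac=0.0, seed=0, d_min=1.8)
        dmap = ded_map(light_obs, dark_obs, toy_model, scale=False)
        nx, ny, nz = dmap.shape
        imin = np.unravel_index(np.argmin(dmap.values), dmap.shape)
        imax = np.unravel_index(np.argmax(dmap.values), dmap.shape)
        cell = toy_model.cell

        def dist(ijk, target):
            frac = np.array(ijk) / np.array([nx, ny, nz])
            dfrac = frac - cell.fractionalize(target)
            dfrac -= np.round(dfrac)
            return np.linalg.norm(cell.orthogonalize(dfrac))

        assert dist(imin, old_pos) < 0.5
        assert dist(imax, old_pos + np.array([1.0, 0.0, 0.0])) < 0.5

    def test_mixture_linearity(self, toy_model):
        # small-displacement regime: a modest 15 degree chi2 rotation
        from trsfx.synthetic import (apply_perturbation,
                                     asn_chi2_perturbation, simulate_dataset)
        small_light = apply_perturbation(toy_model, asn_chi2_perturbation(-15.0))
        maps = {}
        for alpha in (0.2, 1.0):
            dark_obs, light_obs = simulate_dataset(toy_model, small_light, alpha,
                                                   noise_frac=0.0, seed=0,
                                                   d_min=2.0)
            maps[alpha] = ded_map(light_obs, dark_obs, toy_model, scale=False)
        full = maps[1.0].values
        partial = maps[0.2].values
        scale = np.sum(partial * full) / np.sum(full * full)
        assert scale == pytest.approx(0.2, rel=0.05)
        resid = np.linalg.norm(partial - 0.2 * full) / np.linalg.norm(0.2 * full)
        assert resid < 0.25
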