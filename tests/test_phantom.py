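"""Phantom generator: geometry, forward models, misalignment."""

import numpy as np
import pytest

import habitatpipe.phantom as ph
from habitatpipe.registration import dice_coefficient
from habitatpipe.tofts import AIFModel, tofts_concentration

from conftest import uniform_phantom


class TestGeneratePhantom:
    def test_five_habitats_and_necrotic_fraction(self):
        truth = ph.generate_phantom(n_habitats=5, necrotic_fraction=0.37, seed=7)
        labs = np.unique(truth.labels)
        assert set(labs) == {-1, 0, 1, 2, 3, 4, 5}
        frac = (truth.labels == -1).sum() / truth.tumor_mask.sum()
        assert frac == pytest.approx(0.37, abs=0.02)

    def test_single_habitat(self):
        truth = ph.generate_phantom(grid_dims=(24, 24, 6), n_habitats=1,
                                    necrotic_fraction=0.0, seed=1)
        assert set(np.unique(truth.labels)) == {0, 1}

    def test_determinism(self):
        a = ph.generate_phantom(seed=11)
        b = ph.generate_phantom(seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            ph.generate_phantom(grid_dims=(6, 6, 2), n_habitats=8)

    def test_habitat_blobs_are_contiguous(self, small_truth):
        from scipy.ndimage import label as cc_label

        for h in range(1, small_truth.n_habitats + 1):
            _, n_comp = cc_label(small_truth.labels == h)
            assert n_comp == 1

    def test_shuffled_control_breaks_contiguity(self):
        truth = ph.generate_phantom(seed=2, shuffled=True)
        from scipy.ndimage import label as cc_label

        n_comps = [cc_label(truth.labels == h)[1] for h in range(1, 6)]
        assert max(n_comps) > 5

    def test_params_inside_physiological_ranges(self):
        from habitatpipe.habitats import DEFAULT_RANGES

        for par in ph.DEFAULT_HABITAT_TABLE:
            lo, hi = DEFAULT_RANGES["adc"]
            assert lo <= par.adc <= hi
            assert 0 < par.ktrans <= 5
            assert 0 < par.ve <= 1
            assert 0 <= par.vp < 1
            assert 0 < par.suv_fdg <= 20
            assert 0 < par.suv_flt <= 20


class TestSimulateDWI:
    def test_closed_form_signal(self):
        par = ph.HabitatParams(1.0e-3, 0.1, 0.2, 0.01, 1, 1, 1800, 1000)
        truth = uniform_phantom(par)
        dwi = ph.simulate_dwi(truth, ph.AcquisitionConfig())
        vox = np.argwhere(truth.labels == 1)[0]
        sig = dwi.data[tuple(vox)]
        # S(b) = S0 exp(-b ADC): b=0 identity, b=800 closed form
        assert sig[0] == pytest.approx(1000.0)
        assert sig[3] == pytest.approx(1000.0 * np.exp(-0.8), abs=0.01)
        assert sig[3] == pytest.approx(449.33, abs=0.01)

    def test_zero_noise_is_constant_within_habitat(self, small_truth, acq):
        dwi = ph.simulate_dwi(small_truth, acq)
        for h in range(1, small_truth.n_habitats + 1):
            vals = dwi.data[small_truth.labels == h]
            assert np.ptp(vals, axis=0).max() == 0

    def test_rician_noise_reproducible(self, small_truth):
        cfg = ph.AcquisitionConfig(noise_sd=20.0)
        a = ph.simulate_dwi(small_truth, cfg, seed=4)
        b = ph.simulate_dwi(small_truth, cfg, seed=4)
        np.testing.assert_array_equal(a.data, b.data)


class TestSimulateVTR:
    def test_closed_form_saturation_recovery(self):
        par = ph.HabitatParams(1.0e-3, 0.1, 0.2, 0.01, 1, 1, 1800.0, 1000.0)
        truth = uniform_phantom(par)
        vtr = ph.simulate_vtr(truth, ph.AcquisitionConfig())
        vox = tuple(np.argwhere(truth.labels == 1)[0])
        sig = vtr.data[vox]
        assert sig[-1] == pytest.approx(1000 * (1 - np.exp(-5500 / 1800)), abs=1e-9)
        assert sig[-1] == pytest.approx(952.90, abs=0.01)

    def test_tr_limits(self):
        par = ph.HabitatParams(1.0e-3, 0.1, 0.2, 0.01, 1, 1, 1800.0, 1000.0)
        truth = uniform_phantom(par)
        cfg = ph.AcquisitionConfig(tr_list=(0.0, 1e7))
        vtr = ph.simulate_vtr(truth, cfg)
        vox = tuple(np.argwhere(truth.labels == 1)[0])
        assert vtr.data[vox][0] == pytest.approx(0.0)  # TR = 0 -> no signal
        assert vtr.data[vox][1] == pytest.approx(1000.0, rel=1e-6)  # TR -> inf


def oracle_tofts(t, ktrans, ve, vp, aif, dt=0.01):
    """Independent trapezoidal-convolution oracle on a very fine grid."""
    tf = np.arange(0.0, t.max() + dt, dt)
    cp = aif.cp(tf)
    kep = ktrans / 60.0 / ve
    out = np.empty_like(tf)
    for i, ti in enumerate(tf):
        kern = cp[: i + 1] * np.exp(-kep * (ti - tf[: i + 1]))
        out[i] = np.trapezoid(kern, dx=dt)
    ct = vp * cp + ktrans / 60.0 * out
    return np.interp(t, tf, ct)


class TestSimulateDCE:
    def test_no_exchange_no_plasma_is_flat(self, acq):
        aif = AIFModel(onset_time=acq.contrast_onset)
        t = acq.dce_times
        c = tofts_concentration(t, 0.0, 0.5, 0.0, aif)
        assert np.all(c == 0)

    def test_plasma_only_voxel_tracks_aif(self, acq):
        aif = AIFModel(onset_time=acq.contrast_onset)
        t = acq.dce_times
        c = tofts_concentration(t, 0.0, 0.5, 0.05, aif)
        np.testing.assert_allclose(c, 0.05 * aif.cp(t), rtol=1e-12)

    def test_forward_model_matches_independent_oracle(self, acq):
        aif = AIFModel(onset_time=acq.contrast_onset)
        t = acq.dce_times
        c = tofts_concentration(t, 0.25, 0.4, 0.02, aif, dt_fine=0.1)
        ref = oracle_tofts(t, 0.25, 0.4, 0.02, aif)
        assert np.abs(c - ref).max() < 0.005 * ref.max()

    def test_baseline_frames_are_flat(self, small_truth, acq, calibrated_aif):
        dce = ph.simulate_dce(small_truth, calibrated_aif, acq)
        base = dce.data[..., : acq.n_precontrast_frames]
        assert np.ptp(base, axis=-1).max() == 0

    def test_necrotic_enhancement_below_threshold(self, small_truth, acq,
                                                  calibrated_aif):
        from habitatpipe.mapping import enhancement_fraction

        dce = ph.simulate_dce(small_truth, calibrated_aif, acq)
        enh = enhancement_fraction(dce, acq.n_precontrast_frames)
        assert enh[small_truth.labels == -1].max() < 0.25
        assert enh[small_truth.viable_mask].min() > 0.25


class TestSimulatePET:
    def test_uniform_suv_gives_dose_per_weight(self):
        par = ph.HabitatParams(1.0e-3, 0.1, 0.2, 0.01, 1.0, 1.0, 1800, 1000)
        truth = uniform_phantom(par)
        cfg = ph.AcquisitionConfig()
        pet = ph.simulate_pet(truth, cfg, "FDG", psf_fwhm=0.0, pad_mm=0.0)
        inside = pet.data[pet.data > 0]
        np.testing.assert_allclose(
            inside, cfg.injected_dose / cfg.body_weight, rtol=1e-12)

    def test_suv_round_trip(self, small_truth, acq):
        from habitatpipe.mapping import compute_suv

        pet = ph.simulate_pet(small_truth, acq, "FLT", psf_fwhm=0.0, pad_mm=0.0)
        suv = compute_suv(pet, acq.injected_dose, acq.body_weight)
        up = np.kron(small_truth.parameter_map("suv_flt"), np.ones((2, 2, 2)))
        np.testing.assert_allclose(suv.suv, up, rtol=1e-12)

    def test_psf_blur_preserves_interior_mean(self, default_truth, acq):
        from habitatpipe.mapping import compute_suv
        from scipy.ndimage import binary_erosion

        pet = ph.simulate_pet(default_truth, acq, "FDG", psf_fwhm=1.5)
        suv = compute_suv(pet, acq.injected_dose, acq.body_weight)
        up = np.kron((default_truth.labels > 0).astype(float), np.ones((2, 2, 2)))
        pad = [(int(np.ceil(4.0 / s)),) * 2 for s in pet.spacing]
        up = np.pad(up, pad)
        for h in range(1, 6):
            hab = np.kron(default_truth.labels == h, np.ones((2, 2, 2))) > 0
            hab = np.pad(hab, pad)
            interior = binary_erosion(hab, iterations=3)
            if interior.sum() < 20:
                continue
            truth_suv = default_truth.habitat_params[h].suv_fdg
            assert suv.suv[interior].mean() == pytest.approx(truth_suv, rel=0.05)


class TestSimulateHistology:
    def test_single_habitat_rates_homogeneous(self):
        par = ph.HabitatParams(0.8e-3, 0.2, 0.3, 0.02, 1.0, 1.0, 1800, 1000)
        truth = uniform_phantom(par, grid=(24, 24, 4))
        sec = ph.simulate_histology(truth, px_per_voxel=6, seed=1)
        rate = ph._stain_rates(par)["hne_nuclei"]
        vals = sec.maps["hne_nuclei"][sec.valid]
        assert vals.mean() == pytest.approx(rate, rel=0.05)

    def test_zero_rate_gives_zero_map(self, small_truth):
        override = {lab: {"cd31_vessels": 0.0}
                    for lab in small_truth.habitat_params}
        sec = ph.simulate_histology(small_truth, seed=2,
                                    rate_override=override)
        assert sec.maps["cd31_vessels"][sec.valid].sum() == 0

    def test_four_fold_rate_ratio_recovered(self):
        truth = ph.generate_phantom(grid_dims=(32, 32, 6), n_habitats=2,
                                    necrotic_fraction=0.0, seed=9)
        override = {1: {"hne_nuclei": 20.0}, 2: {"hne_nuclei": 5.0}}
        sec = ph.simulate_histology(truth, seed=3, rate_override=override)
        m1 = sec.maps["hne_nuclei"][sec.truth_labels == 1].mean()
        m2 = sec.maps["hne_nuclei"][sec.truth_labels == 2].mean()
        assert m1 / m2 == pytest.approx(4.0, rel=0.1)

    def test_section_outside_tumor_raises(self, small_truth):
        lab = small_truth.labels
        empty = int(np.argwhere([not (lab[:, :, z] != 0).any()
                                 for z in range(lab.shape[2])])[0][0])
        with pytest.raises(ValueError, match="does not intersect"):
            ph.simulate_histology(small_truth, section_index=empty)


class TestApplyMisalignment:
    def test_identity_transform(self, small_truth):
        vol = small_truth.label_volume.with_data(
            small_truth.labels.astype(float))
        out = ph.apply_misalignment(vol, np.eye(4))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-9)

    def test_pure_translation_shifts_centroid(self, default_truth):
        vol = default_truth.label_volume.with_data(
            (default_truth.labels != 0).astype(float))
        a = np.eye(4)
        a[:3, 3] = [2.0, 0.0, 0.0]
        out = ph.apply_misalignment(vol, a)

        def com(v):
            idx = np.indices(v.data.shape).reshape(3, -1).astype(float)
            w = v.data.ravel()
            return v.affine[:3, :3] @ ((idx * w).sum(1) / w.sum()) + v.affine[:3, 3]

        shift = com(out) - com(vol)
        np.testing.assert_allclose(shift, [2.0, 0.0, 0.0], atol=0.05)

    def test_inverse_round_trip_dice(self, default_truth):
        mask = (default_truth.labels != 0).astype(float)
        vol = default_truth.label_volume.with_data(mask)
        rng = np.random.default_rng(0)
        center = default_truth.label_volume.voxel_to_world(
            (np.asarray(mask.shape) - 1) / 2.0)[0]
        a = ph.random_rigid_affine(rng, 1.5, 2.0, center)
        fwd = ph.apply_misalignment(vol, a)
        back = ph.apply_misalignment(fwd, np.linalg.inv(a))
        dice = dice_coefficient(mask > 0.5, back.data > 0.5)
        assert dice >= 0.99

    def test_singular_affine_rejected(self, small_truth):
        vol = small_truth.label_volume.with_data(small_truth.labels.astype(float))
        bad = np.zeros((4, 4))
        with pytest.raises(ValueError, match="invertible"):
            ph.apply_misalignment(vol, bad)
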