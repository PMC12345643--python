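"""Self-contained recovery benchmarks on the digital phantom.

Each function sets up a ground-truth experiment, runs the corresponding
pipeline stage, and returns scalar recovery metrics.  They power both the
acceptance checks in the test suite and the standalone acceptance script;
all randomness is controlled by an explicit seed.
"""

from __future__ import annotations

import numpy as np

from . import habitats as hb
from . import mapping as mp
from . import msi as msi_mod
from . import phantom as ph
from . import registration as reg
from .tofts import AIFModel, tofts_concentration

__all__ = [
    "tofts_recovery",
    "adc_t1_recovery",
    "registration_recovery",
    "habitat_recovery",
    "msi_calibration",
]


def tofts_recovery(n_voxels: int = 500, seed: int = 0,
                   noise_sd: float = 7.5) -> dict:
    """Extended Tofts recovery at 6.4 s sampling.

    Noiseless: one representative voxel per habitat, maximum relative error
    over Ktrans/ve/vp.  Noisy: ``n_voxels`` tumor voxels with Rician noise
    of scale ``noise_sd`` (SNR ~ 20 against the ~150 a.u. DCE baseline),
    full signal-to-concentration + muscle-calibrated AIF chain, median
    absolute relative error of Ktrans and ve.
    """
    rng = np.random.default_rng(seed)
    truth = ph.generate_phantom(seed=int(rng.integers(2**31 - 1)))
    cfg = ph.AcquisitionConfig(noise_sd=noise_sd)
    aif_true = AIFModel(onset_time=cfg.contrast_onset)
    t = cfg.dce_times

    # noiseless: direct forward curves per habitat
    errs = []
    for par in truth.habitat_params.values():
        conc = tofts_concentration(t, par.ktrans, par.ve, par.vp, aif_true)
        fit = mp.fit_extended_tofts(conc, t, aif_true)
        errs += [abs(fit["ktrans"] - par.ktrans) / par.ktrans,
                 abs(fit["ve"] - par.ve) / par.ve]
    noiseless_max = float(np.max(errs))

    # noisy: full chain on sampled voxels
    dce = ph.simulate_dce(truth, aif_true, cfg,
                          seed=int(rng.integers(2**31 - 1)))
    t1 = mp.T1Map(t1=truth.parameter_map("t1", background=np.nan),
                  s0=truth.parameter_map("s0"))
    conc = mp.signal_to_concentration(dce, t1, cfg.n_precontrast_frames)
    muscle_ok = truth.muscle_mask
    muscle_curve = np.nanmean(conc[muscle_ok], axis=0)
    aif_cal = mp.calibrate_aif(AIFModel(), muscle_curve, t)
    idx = np.argwhere(truth.viable_mask)
    pick = idx[rng.choice(len(idx), size=n_voxels, replace=False)]
    kt_err, ve_err = [], []
    for i, j, k in pick:
        par = truth.habitat_params[int(truth.labels[i, j, k])]
        fit = mp.fit_extended_tofts(conc[i, j, k], t, aif_cal)
        if not fit["success"] or not fit["ve_identifiable"]:
            kt_err.append(1.0)
            ve_err.append(1.0)
            continue
        kt_err.append(abs(fit["ktrans"] - par.ktrans) / par.ktrans)
        ve_err.append(abs(fit["ve"] - par.ve) / par.ve)
    return {
        "noiseless_max_rel_err": noiseless_max,
        "ktrans_median_rel_err": float(np.median(kt_err)),
        "ve_median_rel_err": float(np.median(ve_err)),
        "n": int(n_voxels),
    }


def adc_t1_recovery(seed: int = 0, snr: float = 30.0) -> dict:
    """ADC and T1 recovery: noiseless maxima and noisy medians.

    Noise is Rician (ADC) / Gaussian (T1) at scale S0/snr (S0 = 1000 a.u.).
    """
    truth = ph.generate_phantom(grid_dims=(32, 32, 6), seed=seed)
    mask = truth.viable_mask
    adc_true = truth.parameter_map("adc")
    t1_true = truth.parameter_map("t1")

    clean = ph.AcquisitionConfig()
    adc0 = mp.fit_adc(ph.simulate_dwi(truth, clean))
    t10 = mp.fit_t1(ph.simulate_vtr(truth, clean), mask=mask)
    adc0_err = np.abs(adc0.adc[mask] - adc_true[mask]) / adc_true[mask]
    t10_err = np.abs(t10.t1[mask] - t1_true[mask]) / t1_true[mask]

    noisy = ph.AcquisitionConfig(noise_sd=1000.0 / snr)
    adc1 = mp.fit_adc(ph.simulate_dwi(truth, noisy, seed=seed + 1))
    t11 = mp.fit_t1(ph.simulate_vtr(truth, noisy, seed=seed + 2), mask=mask)
    adc1_err = np.abs(adc1.adc[mask] - adc_true[mask]) / adc_true[mask]
    t11_err = np.abs(t11.t1[mask] - t1_true[mask]) / t1_true[mask]
    return {
        "adc_noiseless_max_rel_err": float(np.nanmax(adc0_err)),
        "t1_noiseless_max_rel_err": float(np.nanmax(t10_err)),
        "adc_noisy_median_rel_err": float(np.nanmedian(adc1_err)),
        "t1_noisy_median_rel_err": float(np.nanmedian(t11_err)),
        "n": int(mask.sum()),
    }


def registration_recovery(n_runs: int = 20, seed: int = 0,
                          max_translation: float = 3.0,
                          max_rotation: float = 5.0) -> dict:
    """Post-registration tumor Dice over random rigid misalignments."""
    rng = np.random.default_rng(seed)
    truth = ph.generate_phantom(seed=int(rng.integers(2**31 - 1)))
    cfg = ph.AcquisitionConfig()
    pet = ph.simulate_pet(truth, cfg, "FDG", psf_fwhm=1.0)
    ref = ph.simulate_dwi(truth, cfg).frame(0)
    center = truth.label_volume.voxel_to_world(
        (np.asarray(truth.labels.shape) - 1) / 2.0)[0]
    dices = []
    for _ in range(n_runs):
        a = ph.random_rigid_affine(rng, max_translation, max_rotation, center)
        mis = ph.apply_misalignment(pet, a)
        down = reg.downsample_antialias(reg.reframe_slices(mis, 1.0),
                                        (0.53, 0.53, 1.0))
        mt = ph.misaligned_tumor_mask(truth, down, a)
        res = reg.register_affine_mi(ref, down, weight_roi=truth.tumor_mask,
                                     fixed_tumor=truth.tumor_mask,
                                     moving_tumor=mt)
        dices.append(res.dice_after)
    dices = np.asarray(dices)
    return {
        "dice": dices.tolist(),
        "n_pass": int((dices >= 0.9).sum()),
        "median_dice": float(np.median(dices)),
        "n": int(n_runs),
    }


def habitat_recovery(seed: int = 0, separation: float = 3.0) -> dict:
    """Cohort-level habitat discovery: silhouette k selection and ARI."""
    from sklearn.metrics import adjusted_rand_score

    df, truth_labels = ph.sample_feature_cohort(
        n_subjects=4, n_timepoints=2, separation=separation, seed=seed)
    fm = hb.FeatureMatrix.from_dataframe(df)
    k_sel = hb.select_k(fm, range(2, 9), seed=seed)
    model = hb.cluster(fm, k=5, seed=seed)
    ari = adjusted_rand_score(truth_labels, model.assignments)
    return {"selected_k": int(k_sel), "ari": float(ari), "n": len(fm)}


def msi_calibration(n_replicates: int = 50, n_perm: int = 150,
                    seed: int = 0) -> dict:
    """Null calibration (shuffled labels) and planted-contiguity signal."""
    rng = np.random.default_rng(seed)
    zbars = []
    for _ in range(n_replicates):
        truth = ph.generate_phantom(grid_dims=(32, 32, 6), shuffled=True,
                                    seed=int(rng.integers(2**31 - 1)))
        lab = np.where(truth.labels > 0, truth.labels, 0)
        m = msi_mod.count_pairs(lab, 6)
        mean, sd = msi_mod.randomized_null(
            lab, n=n_perm, seed=int(rng.integers(2**31 - 1)))
        m = msi_mod.msi_zscores(m, mean, sd)
        zbars.append(np.nanmean(m.diagonal_z))
    truth = ph.generate_phantom(seed=int(rng.integers(2**31 - 1)))
    lab = np.where(truth.labels > 0, truth.labels, 0)
    m = msi_mod.count_pairs(lab, 6)
    mean, sd = msi_mod.randomized_null(lab, n=1000,
                                       seed=int(rng.integers(2**31 - 1)))
    m = msi_mod.msi_zscores(m, mean, sd)
    return {
        "shuffled_mean_diagonal_z": float(np.mean(zbars)),
        "planted_mean_diagonal_z": float(np.nanmean(m.diagonal_z)),
        "n": int(n_replicates),
    }
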