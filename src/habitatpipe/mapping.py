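"""Voxel-wise quantitative parametric mapping.

Fits the four quantitative maps the habitat analysis consumes and applies
the physiological exclusion rules:

* ADC from multi-b-value DWI, ``S(b) = S0 exp(-b ADC)``, by log-linear least
  squares, with per-slice exclusion of artifact slices;
* T1 from variable-TR saturation recovery, ``S = S0 (1 - exp(-TR/T1))``, by
  nonlinear least squares (variable projection over S0);
* Extended Tofts ``Ktrans, ve, vp`` from DCE concentration curves with a
  muscle-calibrated population AIF, plus range / enhancement filtering
  (Ktrans 0-5 min^-1, ve and vp 0-1, enhancement >= 25% over baseline);
* SUV from PET activity, ``SUV = activity / (injected dose / body weight)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .tofts import (
    AIFModel,
    spgr_invert_to_concentration,
    tofts_concentration,
)
from .volume import ImageVolume

__all__ = [
    "ADCMap",
    "T1Map",
    "ToftsMap",
    "SUVMap",
    "fit_adc",
    "exclude_dwi_slices",
    "fit_t1",
    "signal_to_concentration",
    "enhancement_fraction",
    "calibrate_aif",
    "fit_extended_tofts",
    "fit_tofts_volume",
    "filter_dce_voxels",
    "compute_suv",
]

# Physiological plausibility bounds for the Tofts fit / filter
KTRANS_RANGE = (0.0, 5.0)  # min^-1
VE_RANGE = (0.0, 1.0)
VP_RANGE = (0.0, 1.0)
MIN_ENHANCEMENT = 0.25  # fractional increase over baseline


@dataclass
class ADCMap:
    """Apparent diffusion coefficient map (mm^2/s) with excluded slices."""

    adc: np.ndarray
    s0: np.ndarray
    excluded_slices: list[int] = field(default_factory=list)
    affine: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        ok = np.isfinite(self.adc)
        if self.excluded_slices:
            ok = ok.copy()
            ok[:, :, self.excluded_slices] = False
        return ok


@dataclass
class T1Map:
    t1: np.ndarray  # ms, NaN where the fit failed or was non-positive
    s0: np.ndarray
    affine: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t1) & (self.t1 > 0)


@dataclass
class ToftsMap:
    """Extended Tofts parameter maps plus validity bookkeeping."""

    ktrans: np.ndarray  # min^-1
    ve: np.ndarray
    vp: np.ndarray
    enhancement: np.ndarray  # fractional signal increase over baseline
    valid: np.ndarray
    exclusion_fraction: float | None = None
    affine: np.ndarray | None = None


@dataclass
class SUVMap:
    suv: np.ndarray
    injected_dose: float
    body_weight: float
    affine: np.ndarray | None = None


def fit_adc(dwi: ImageVolume, b_values=None) -> ADCMap:
    """Log-linear least-squares ADC fit per voxel.

    The slope of ``ln S(b)`` against ``b`` is ``-ADC``; ``S0`` is recovered
    from the intercept.  Voxels with any non-positive signal are invalid
    (NaN), never an exception.
    """
    b = np.asarray(
        dwi.frame_times if b_values is None else b_values, dtype=float
    )
    if len(b) < 2 or b[0] != 0:
        raise ValueError("need >= 2 b-values including b = 0")
    sig = np.asarray(dwi.data, dtype=float)
    if sig.shape[-1] != len(b):
        raise ValueError("frame count does not match b-values")
    ok = np.all(sig > 0, axis=-1)
    lns = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    bm = b - b.mean()
    denom = (bm**2).sum()
    slope = (lns * bm).sum(axis=-1) / denom
    intercept = lns.mean(axis=-1) - slope * b.mean()
    adc = np.where(ok, -slope, np.nan)
    s0 = np.where(ok, np.exp(intercept), np.nan)
    return ADCMap(adc=adc, s0=s0, affine=dwi.affine.copy())


def exclude_dwi_slices(adc_map: ADCMap, tumor: np.ndarray) -> ADCMap:
    """Mark artifact slices for exclusion from the ADC analysis.

    A slice is excluded when its within-tumor mean ADC strictly exceeds the
    median of all tumor-voxel ADC values plus two standard deviations.
    """
    tumor = np.asarray(tumor, dtype=bool)
    vals = adc_map.adc[tumor]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("tumor mask contains no valid ADC voxels")
    slices = [z for z in range(tumor.shape[2]) if tumor[:, :, z].any()]
    if len(slices) < 2:
        warnings.warn("single-slice tumor: no slice exclusion possible")
        return replace(adc_map, excluded_slices=[])
    threshold = np.median(vals) + 2.0 * vals.std(ddof=0)
    excluded = []
    for z in slices:
        m = tumor[:, :, z]
        sv = adc_map.adc[:, :, z][m]
        sv = sv[np.isfinite(sv)]
        if sv.size and sv.mean() > threshold:
            excluded.append(z)
    return replace(adc_map, excluded_slices=excluded)


def _fit_t1_voxel(tr: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Variable-projection NLLS for ``S = S0 (1 - exp(-TR/T1))``.

    For fixed T1 the optimal S0 is linear; the 1-D profile over T1 is
    minimised by bounded scalar optimisation.
    """

    def sse(t1: float) -> float:
        g = 1.0 - np.exp(-tr / t1)
        s0 = (g @ y) / (g @ g)
        r = s0 * g - y
        return float(r @ r)

    res = optimize.minimize_scalar(
        sse, bounds=(1.0, 30000.0), method="bounded",
        options={"xatol": 1e-3},
    )
    if not res.success:
        return np.nan, np.nan
    t1 = float(res.x)
    g = 1.0 - np.exp(-tr / t1)
    s0 = float((g @ y) / (g @ g))
    if s0 <= 0 or t1 <= 0 or t1 >= 29999.0:
        return np.nan, np.nan
    return t1, s0


def fit_t1(vtr: ImageVolume, tr_list=None, mask: np.ndarray | None = None) -> T1Map:
    """Voxel-wise nonlinear saturation-recovery T1 fit.

    Non-convergent, degenerate (flat / all-zero) or non-positive results are
    invalid (NaN).  ``mask`` restricts fitting (e.g. to tumor + muscle).
    """
    tr = np.asarray(vtr.frame_times if tr_list is None else tr_list, dtype=float)
    if len(tr) < 3:
        raise ValueError("need at least 3 TR values")
    sig = np.asarray(vtr.data, dtype=float)
    shape = sig.shape[:3]
    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    if mask is None:
        mask = sig.max(axis=-1) > 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        y = sig[i, j, k]
        if not np.all(np.isfinite(y)) or y.max() <= 0 or np.ptp(y) == 0:
            continue
        t1[i, j, k], s0[i, j, k] = _fit_t1_voxel(tr, y)
    return T1Map(t1=t1, s0=s0, affine=vtr.affine.copy())


def signal_to_concentration(
    dce: ImageVolume,
    t1_map: T1Map,
    baseline_frames: int,
    relaxivity: float = 4.5,
    tr_ms: float = 100.0,
    flip_deg: float = 30.0,
) -> np.ndarray:
    """Convert DCE signal to contrast concentration (mM), voxel-wise.

    SPGR steady-state inversion using the pre-contrast T1 and the mean of
    the first ``baseline_frames`` frames as baseline; invalid-T1 voxels are
    NaN throughout, and concentrations are clipped at zero (baseline frames
    map to C ~ 0).
    """
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    sig = np.asarray(dce.data, dtype=float)
    base = sig[..., :baseline_frames].mean(axis=-1)
    t10_s = t1_map.t1 / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = spgr_invert_to_concentration(
            sig, base[..., None], t10_s[..., None], tr_ms / 1000.0, flip_deg,
            relaxivity,
        )
        conc = np.where(np.isfinite(conc), np.clip(conc, 0.0, None), np.nan)
    conc[~t1_map.valid] = np.nan
    return conc


def enhancement_fraction(dce: ImageVolume, baseline_frames: int,
                         smooth_frames: int = 5) -> np.ndarray:
    """Peak fractional signal increase over the pre-contrast baseline.

    The post-contrast curve is boxcar-smoothed over ``smooth_frames`` before
    taking the peak, so the estimate reflects sustained enhancement rather
    than single-frame noise excursions.
    """
    sig = np.asarray(dce.data, dtype=float)
    base = sig[..., :baseline_frames].mean(axis=-1)
    post = sig[..., baseline_frames:]
    w = min(smooth_frames, post.shape[-1])
    if w > 1:
        cs = np.cumsum(post, axis=-1)
        head = cs[..., w - 1 :]
        tail = np.concatenate(
            [np.zeros_like(cs[..., :1]), cs[..., :-w]], axis=-1)
        post = (head - tail) / w  # all length-w moving averages
    peak = post.max(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        enh = np.where(base > 0, peak / base - 1.0, np.nan)
    return enh


def detect_arrival(curve: np.ndarray, t: np.ndarray,
                   init_baseline: int = 10) -> float:
    """Contrast arrival time: last sample before the curve first exceeds
    the bolus-detection threshold.

    The threshold is baseline mean + 3 baseline SD, floored at 5% of the
    curve's dynamic range so that sub-noise blips in a heavily averaged
    curve cannot trigger a false arrival.
    """
    curve = np.asarray(curve, dtype=float)
    base = curve[:init_baseline]
    span = curve.max() - base.mean()
    if span <= 0:
        raise ValueError("no contrast arrival detected (flat curve)")
    thr = base.mean() + max(3.0 * base.std(ddof=0), 0.05 * span) + 1e-12
    above = np.nonzero(curve > thr)[0]
    above = above[above >= init_baseline]
    if len(above) == 0:
        raise ValueError("no contrast arrival detected (flat curve)")
    return float(t[above[0] - 1])


def calibrate_aif(
    population_aif: AIFModel,
    muscle_curve: np.ndarray,
    t: np.ndarray,
    muscle_ktrans: float = 0.1,
    muscle_ve: float = 0.1,
    muscle_vp: float = 0.02,
) -> AIFModel:
    """Per-scan AIF calibration against a skeletal-muscle reference region.

    The bolus arrival sets ``onset_time``; the amplitude scale is the least-
    squares factor matching the Extended Tofts prediction for muscle (fixed
    literature exchange parameters) to the observed muscle concentration
    curve.  Raises on a flat muscle curve.
    """
    t = np.asarray(t, dtype=float)
    muscle_curve = np.asarray(muscle_curve, dtype=float)
    if np.ptp(muscle_curve) <= 0:
        raise ValueError("flat muscle curve: AIF calibration failed")
    onset = detect_arrival(muscle_curve, t)
    aif1 = population_aif.with_calibration(amplitude_scale=1.0, onset_time=onset)
    pred = tofts_concentration(t, muscle_ktrans, muscle_ve, muscle_vp, aif1)
    denom = float(pred @ pred)
    if denom <= 0:
        raise ValueError("degenerate muscle prediction: AIF calibration failed")
    scale = float(pred @ muscle_curve) / denom
    if scale <= 0:
        raise ValueError("non-positive AIF scale: AIF calibration failed")
    return population_aif.with_calibration(amplitude_scale=scale, onset_time=onset)


def _tofts_residual_jac(x, t, cp, conc):
    ktrans, ve, vp = x
    kt_s = ktrans / 60.0
    ve = max(ve, 1e-9)
    kep = kt_s / ve
    n = len(t)
    dt = t[1] - t[0]
    lag = np.clip(t[:, None] - t[None, :], 0.0, None)
    w = np.full((n, n), dt)
    w[:, 0] = 0.5 * dt
    np.fill_diagonal(w, 0.5 * dt)
    ew = np.tril(np.exp(-kep * lag) * w)
    conv = ew @ cp
    conv[0] = 0.0
    dconv = -(np.tril(lag * np.exp(-kep * lag) * w) @ cp)  # dI/dkep
    dconv[0] = 0.0
    model = vp * cp + kt_s * conv
    r = model - conc
    jac = np.empty((n, 3))
    # dkep/dktrans = 1/(60 ve); dkep/dve = -ktrans/(60 ve^2)
    jac[:, 0] = conv / 60.0 + kt_s * dconv / (60.0 * ve)
    jac[:, 1] = kt_s * dconv * (-ktrans / (60.0 * ve**2))
    jac[:, 2] = cp
    return r, jac


def fit_extended_tofts(
    conc: np.ndarray,
    t: np.ndarray,
    aif: AIFModel,
    x0: tuple[float, float, float] = (0.1, 0.2, 0.01),
    max_nfev: int = 200,
) -> dict:
    """Bounded NLLS Extended Tofts fit of a single voxel concentration curve.

    Bounds: Ktrans in [0, 5] min^-1, ve in (0, 1], vp in [0, 1).  The model
    convolution is evaluated by discrete trapezoidal quadrature on the
    acquisition grid.  Returns a dict with ``ktrans, ve, vp, success`` and
    ``ve_identifiable`` (False for curves with no measurable exchange).
    """
    t = np.asarray(t, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if not np.all(np.isfinite(conc)):
        return {"ktrans": np.nan, "ve": np.nan, "vp": np.nan,
                "success": False, "ve_identifiable": False}
    cp = aif.cp(t)
    res = optimize.least_squares(
        lambda x: _tofts_residual_jac(x, t, cp, conc)[0],
        x0=np.asarray(x0, dtype=float),
        jac=lambda x: _tofts_residual_jac(x, t, cp, conc)[1],
        bounds=([0.0, 1e-6, 0.0], [5.0, 1.0, 1.0 - 1e-9]),
        xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=max_nfev,
    )
    ktrans, ve, vp = res.x
    identifiable = True
    # polish against the exact no-exchange solution (linear in vp): curves
    # with no measurable exchange otherwise stall at a tiny spurious ktrans
    cpc = float(cp @ cp)
    if cpc > 0:
        vp0 = float(np.clip((cp @ conc) / cpc, 0.0, 1.0 - 1e-9))
        r0 = vp0 * cp - conc
        if r0 @ r0 <= res.fun @ res.fun + 1e-15:
            ktrans, ve, vp = 0.0, np.nan, vp0
    if ktrans < 1e-4:
        ktrans = 0.0
        ve = np.nan  # no exchange: ve cannot be estimated
        identifiable = False
    return {"ktrans": float(ktrans), "ve": float(ve) if np.isfinite(ve) else np.nan,
            "vp": float(vp), "success": bool(res.success),
            "ve_identifiable": identifiable}


def fit_tofts_volume(
    conc: np.ndarray,
    t: np.ndarray,
    aif: AIFModel,
    dce: ImageVolume,
    baseline_frames: int,
    mask: np.ndarray | None = None,
) -> ToftsMap:
    """Fit the Extended Tofts model over a volume and attach enhancement."""
    shape = conc.shape[:3]
    ktr = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    if mask is None:
        mask = np.all(np.isfinite(conc), axis=-1)
    else:
        mask = mask & np.all(np.isfinite(conc), axis=-1)
    for i, j, k in np.argwhere(mask):
        fit = fit_extended_tofts(conc[i, j, k], t, aif)
        if fit["success"]:
            ktr[i, j, k] = fit["ktrans"]
            ve[i, j, k] = fit["ve"]
            vp[i, j, k] = fit["vp"]
    enh = enhancement_fraction(dce, baseline_frames)
    valid = np.isfinite(ktr) & np.isfinite(ve) & np.isfinite(vp)
    return ToftsMap(ktrans=ktr, ve=ve, vp=vp, enhancement=enh, valid=valid,
                    affine=dce.affine.copy())


def filter_dce_voxels(
    tmap: ToftsMap,
    ktrans_range=KTRANS_RANGE,
    ve_range=VE_RANGE,
    vp_range=VP_RANGE,
    min_enhancement: float = MIN_ENHANCEMENT,
) -> ToftsMap:
    """Apply physiological range and enhancement filters (idempotent).

    Voxels with Ktrans, ve or vp outside their ranges, or with less than
    ``min_enhancement`` fractional signal increase over baseline, lose their
    validity flag.  The exclusion fraction is reported relative to the
    voxels that entered the filter.
    """
    before = tmap.valid.copy()
    with np.errstate(invalid="ignore"):
        ok = (
            before
            & (tmap.ktrans >= ktrans_range[0]) & (tmap.ktrans <= ktrans_range[1])
            & (tmap.ve >= ve_range[0]) & (tmap.ve <= ve_range[1])
            & (tmap.vp >= vp_range[0]) & (tmap.vp <= vp_range[1])
            & (tmap.enhancement >= min_enhancement)
        )
    n_before = int(before.sum())
    frac = float((n_before - ok.sum()) / n_before) if n_before else 0.0
    if tmap.exclusion_fraction is not None:
        # already filtered once: keep the original denominator
        frac = tmap.exclusion_fraction if np.array_equal(ok, before) else frac
    return replace(tmap, valid=ok, exclusion_fraction=frac)


def compute_suv(activity: ImageVolume, injected_dose: float,
                body_weight: float) -> SUVMap:
    """Standardised uptake value: activity normalised by dose per body weight."""
    if injected_dose <= 0 or body_weight <= 0:
        raise ValueError("injected_dose and body_weight must be positive")
    suv = np.asarray(activity.data, dtype=float) / (injected_dose / body_weight)
    return SUVMap(suv=suv, injected_dose=float(injected_dose),
                  body_weight=float(body_weight), affine=activity.affine.copy())
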