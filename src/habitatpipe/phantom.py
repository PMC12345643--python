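"""Digital tumor phantom with known multiparametric habitats.

The phantom emulates a preclinical flank-tumor PET/MRI study: an ellipsoidal
tumor partitioned into spatially contiguous physiological habitats (plus a
central necrotic core and a skeletal-muscle reference slab), from which the
module synthesises every acquisition the analysis consumes — multi-b-value
DWI, variable-TR T1 series, dynamic contrast-enhanced MRI, static PET
activity volumes for two tracers, and matched 2D stain-density histology
sections.  Every generated quantity derives from a known per-habitat
parameter tuple, so all downstream fitting, registration and clustering
stages can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .tofts import AIFModel, spgr_signal, tofts_concentration
from .volume import ImageVolume

__all__ = [
    "HabitatParams",
    "AcquisitionConfig",
    "PhantomTruth",
    "generate_phantom",
    "simulate_dwi",
    "simulate_vtr",
    "simulate_dce",
    "simulate_pet",
    "simulate_histology",
    "apply_misalignment",
    "random_rigid_affine",
    "sample_feature_cohort",
    "DEFAULT_HABITAT_TABLE",
]

FEATURES = ("adc", "ktrans", "ve", "suv_fdg", "suv_flt")


@dataclass(frozen=True)
class HabitatParams:
    """Generative physiological parameters of one habitat.

    Units: ``adc`` mm^2/s, ``ktrans`` min^-1, ``ve``/``vp`` unitless volume
    fractions, SUV unitless, ``t1`` ms, ``s0`` arbitrary signal units.
    """

    adc: float
    ktrans: float
    ve: float
    vp: float
    suv_fdg: float
    suv_flt: float
    t1: float
    s0: float

    def features(self) -> np.ndarray:
        """The five clustering features (ADC, Ktrans, ve, FDG-SUV, FLT-SUV)."""
        return np.array([self.adc, self.ktrans, self.ve, self.suv_fdg, self.suv_flt])


# Archetype habitats.  The first five mirror the physiological phenotypes the
# analysis is designed to discover: high vascularity (HV), hypoxic responding
# (HRSP), transitional zone (TZ), active tumor (ATMR) and responding (RSP).
# All values sit inside the physiological filter ranges used downstream.
DEFAULT_HABITAT_TABLE: tuple[HabitatParams, ...] = (
    HabitatParams(0.70e-3, 0.44, 0.45, 0.050, 1.5, 1.5, 2000.0, 1000.0),  # HV
    HabitatParams(0.90e-3, 0.05, 0.60, 0.010, 0.8, 1.0, 2200.0, 1000.0),  # HRSP
    HabitatParams(1.30e-3, 0.15, 0.30, 0.020, 1.2, 1.2, 2400.0, 1000.0),  # TZ
    HabitatParams(0.60e-3, 0.08, 0.20, 0.020, 2.5, 2.5, 1800.0, 1000.0),  # ATMR
    HabitatParams(0.50e-3, 0.03, 0.15, 0.010, 0.6, 0.5, 1700.0, 1000.0),  # RSP
    HabitatParams(1.00e-3, 0.30, 0.35, 0.030, 1.8, 0.9, 2100.0, 1000.0),
    HabitatParams(0.80e-3, 0.60, 0.25, 0.060, 1.0, 2.0, 1900.0, 1000.0),
    HabitatParams(1.50e-3, 0.10, 0.50, 0.015, 0.4, 0.8, 2300.0, 1000.0),
)

# Necrotic tissue: essentially no contrast exchange, so its DCE enhancement
# stays far below the 25% viability threshold; high ADC, no tracer trapping.
NECROTIC_PARAMS = HabitatParams(2.0e-3, 0.002, 0.20, 0.001, 0.3, 0.2, 2800.0, 900.0)
# Skeletal muscle reference used for AIF calibration (literature-level
# exchange parameters; the calibration assumes ktrans=0.1, ve=0.1).
MUSCLE_PARAMS = HabitatParams(1.40e-3, 0.10, 0.10, 0.020, 0.5, 0.3, 1500.0, 800.0)


@dataclass
class AcquisitionConfig:
    """Acquisition protocol and noise settings for the simulated study.

    Defaults follow the reference small-animal protocol: four b-values
    (0/150/500/800 s/mm^2), six saturation-recovery TRs (255..5500 ms), DCE
    at 6.4 s temporal resolution with 20 pre-contrast frames, and PET doses
    of ~3.7 MBq in a ~25 g mouse.
    """

    b_values: tuple[float, ...] = (0.0, 150.0, 500.0, 800.0)
    tr_list: tuple[float, ...] = (255.0, 400.0, 800.0, 1500.0, 3000.0, 5500.0)
    dce_temporal_resolution: float = 6.4  # s
    n_precontrast_frames: int = 20
    n_dce_frames: int = 70
    dce_tr: float = 100.0  # ms, FLASH readout
    dce_flip_deg: float = 30.0
    relaxivity: float = 4.5  # s^-1 mM^-1 at 9.4 T
    injected_dose: float = 3700.0  # kBq
    body_weight: float = 25.0  # g
    noise_sd: float = 0.0  # a.u., MRI magnitude noise scale
    pet_noise_sd: float = 0.0  # activity units
    misalignment: np.ndarray | None = None  # 4x4 world affine

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, float)
        tr = np.asarray(self.tr_list, float)
        if not (np.all(np.diff(b) > 0) and np.all(np.diff(tr) > 0)):
            raise ValueError("b_values and tr_list must be strictly increasing")
        if self.dce_temporal_resolution <= 0:
            raise ValueError("dce_temporal_resolution must be positive")
        if self.n_precontrast_frames < 1:
            raise ValueError("need at least one pre-contrast frame")

    @property
    def dce_times(self) -> np.ndarray:
        return np.arange(self.n_dce_frames) * self.dce_temporal_resolution

    @property
    def contrast_onset(self) -> float:
        """Contrast arrival time (s): immediately after the baseline frames."""
        return self.n_precontrast_frames * self.dce_temporal_resolution


@dataclass
class PhantomTruth:
    """Ground-truth habitat geometry and generative parameters.

    ``label_volume`` uses 0 for background, -1 for the necrotic core and
    1..n for viable habitats.  ``muscle_mask`` marks the reference muscle
    slab (not part of the tumor labels).
    """

    label_volume: ImageVolume
    habitat_params: dict[int, HabitatParams]
    grid_spacing: tuple[float, float, float]
    seed: int
    necrotic_params: HabitatParams = NECROTIC_PARAMS
    muscle_params: HabitatParams = MUSCLE_PARAMS
    muscle_mask: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.label_volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.label_volume.affine

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels != 0

    @property
    def viable_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_habitats(self) -> int:
        return int(self.labels.max())

    def parameter_map(self, name: str, background: float = 0.0) -> np.ndarray:
        """Voxel map of one generative parameter across all tissue classes."""
        out = np.full(self.labels.shape, background, dtype=float)
        for lab, par in self.habitat_params.items():
            out[self.labels == lab] = getattr(par, name)
        out[self.labels == -1] = getattr(self.necrotic_params, name)
        if self.muscle_mask is not None:
            out[self.muscle_mask] = getattr(self.muscle_params, name)
        return out


def _ellipsoid_radius(shape, spacing, semi_axes_mm):
    """Normalised ellipsoid radius field (1.0 on the surface)."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    r2 = np.zeros(shape, dtype=float)
    for g, c, sp, ax in zip(grids, center, spacing, semi_axes_mm):
        r2 += ((g - c) * sp / ax) ** 2
    return np.sqrt(r2)


def generate_phantom(
    grid_dims: tuple[int, int, int] = (64, 64, 10),
    n_habitats: int = 5,
    necrotic_fraction: float = 0.37,
    seed: int = 0,
    spacing: tuple[float, float, float] = (0.53, 0.53, 1.0),
    habitat_params: tuple[HabitatParams, ...] | None = None,
    shuffled: bool = False,
    with_muscle: bool = True,
) -> PhantomTruth:
    """Generate an ellipsoidal tumor partitioned into contiguous habitats.

    Habitats are grown as Voronoi cells of random seed points inside the
    viable shell of the tumor (a central core of ``necrotic_fraction`` of
    tumor voxels is labelled necrotic, -1).  ``shuffled=True`` destroys
    spatial contiguity by permuting labels across viable voxels — a
    non-contiguous control for spatial-interaction null testing.

    Deterministic for fixed ``seed``.
    """
    if not 2 <= n_habitats <= 8:
        if n_habitats != 1:  # single-habitat phantoms allowed for degenerate tests
            raise ValueError("n_habitats must be in [1, 8]")
    if not 0 <= necrotic_fraction < 0.8:
        raise ValueError("necrotic_fraction must be in [0, 0.8)")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in grid_dims)
    spacing = tuple(float(s) for s in spacing)
    fov = [n * sp for n, sp in zip(shape, spacing)]
    semi_axes = (0.36 * fov[0], 0.36 * fov[1], 0.36 * fov[2])
    radius = _ellipsoid_radius(shape, spacing, semi_axes)
    tumor = radius < 1.0
    n_tumor = int(tumor.sum())
    if n_tumor < 10 * n_habitats:
        raise ValueError(
            f"grid {shape} too small: {n_tumor} tumor voxels for {n_habitats} habitats"
        )

    labels = np.zeros(shape, dtype=np.int16)
    # central necrotic core: innermost necrotic_fraction of tumor voxels
    if necrotic_fraction > 0:
        cut = np.quantile(radius[tumor], necrotic_fraction)
        necrotic = tumor & (radius < cut)
        labels[necrotic] = -1
    viable = tumor & (labels == 0)
    viable_idx = np.argwhere(viable)
    if len(viable_idx) < n_habitats:
        raise ValueError("grid too small to place distinct habitat seed points")
    coords_mm = viable_idx * np.asarray(spacing)
    seeds = viable_idx[rng.choice(len(viable_idx), size=n_habitats, replace=False)]
    seeds_mm = seeds * np.asarray(spacing)
    d = ((coords_mm[:, None, :] - seeds_mm[None, :, :]) ** 2).sum(axis=2)
    assign = d.argmin(axis=1) + 1
    labels[tuple(viable_idx.T)] = assign
    if shuffled:
        vals = labels[viable]
        labels[viable] = rng.permutation(vals)

    table = habitat_params if habitat_params is not None else DEFAULT_HABITAT_TABLE
    params = {i + 1: table[i] for i in range(n_habitats)}

    affine = np.diag([*spacing, 1.0])
    muscle = None
    if with_muscle:
        muscle = np.zeros(shape, dtype=bool)
        x0 = max(1, shape[0] // 16)
        muscle[x0 : x0 + max(2, shape[0] // 12),
               shape[1] // 4 : 3 * shape[1] // 4, :] = True
        muscle &= ~tumor
    return PhantomTruth(
        label_volume=ImageVolume(labels, affine),
        habitat_params=params,
        grid_spacing=spacing,
        seed=int(seed),
        muscle_mask=muscle,
    )


def _rician(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rician magnitude noise: |(S + n1) + i n2| with n ~ N(0, sd)."""
    if sd <= 0:
        return signal
    n1 = rng.normal(0.0, sd, signal.shape)
    n2 = rng.normal(0.0, sd, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_dwi(truth: PhantomTruth, cfg: AcquisitionConfig,
                 seed: int = 0) -> ImageVolume:
    """Multi-b-value DWI: ``S(b) = S0 exp(-b ADC)`` plus Rician noise."""
    adc = truth.parameter_map("adc")
    s0 = truth.parameter_map("s0")
    rng = np.random.default_rng(seed)
    b = np.asarray(cfg.b_values, float)
    frames = s0[..., None] * np.exp(-b[None, None, None, :] * adc[..., None])
    frames = _rician(frames, cfg.noise_sd, rng)
    return ImageVolume(frames, truth.affine.copy(), frame_times=b)


def simulate_vtr(truth: PhantomTruth, cfg: AcquisitionConfig,
                 seed: int = 0) -> ImageVolume:
    """Variable-TR saturation recovery: ``S = S0 (1 - exp(-TR/T1))`` + noise."""
    t1 = truth.parameter_map("t1", background=np.inf)
    s0 = truth.parameter_map("s0")
    rng = np.random.default_rng(seed)
    tr = np.asarray(cfg.tr_list, float)
    with np.errstate(divide="ignore"):
        frames = s0[..., None] * (1.0 - np.exp(-tr[None, None, None, :] / t1[..., None]))
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, frames.shape)
    return ImageVolume(frames, truth.affine.copy(), frame_times=tr)


def simulate_dce(truth: PhantomTruth, aif: AIFModel, cfg: AcquisitionConfig,
                 seed: int = 0) -> ImageVolume:
    """Dynamic contrast-enhanced series from the Extended Tofts forward model.

    Concentration curves are computed per tissue class on a fine time grid
    (0.1 s) and converted to signal with the same SPGR model the fitting
    stage inverts; the first ``n_precontrast_frames`` frames are pure
    baseline.  Necrotic voxels enhance far below the 25% viability cut.
    """
    t = cfg.dce_times
    if aif.onset_time <= 0:
        aif = aif.with_calibration(onset_time=cfg.contrast_onset)
    rng = np.random.default_rng(seed)
    shape = truth.labels.shape
    frames = np.zeros(shape + (len(t),), dtype=float)
    classes: list[tuple[np.ndarray, HabitatParams]] = [
        (truth.labels == lab, par) for lab, par in truth.habitat_params.items()
    ]
    classes.append((truth.labels == -1, truth.necrotic_params))
    if truth.muscle_mask is not None:
        classes.append((truth.muscle_mask, truth.muscle_params))
    for mask, par in classes:
        if not mask.any():
            continue
        conc = tofts_concentration(t, par.ktrans, par.ve, par.vp, aif, dt_fine=0.1)
        r1 = 1.0 / (par.t1 / 1000.0) + cfg.relaxivity * conc
        sig = spgr_signal(r1, par.s0, cfg.dce_tr / 1000.0, cfg.dce_flip_deg)
        frames[mask] = sig
    frames = _rician(frames, cfg.noise_sd, rng)
    return ImageVolume(frames, truth.affine.copy(), frame_times=t)


def simulate_pet(
    truth: PhantomTruth,
    cfg: AcquisitionConfig,
    tracer: str = "FDG",
    psf_fwhm: float = 0.0,
    seed: int = 0,
    upsample: tuple[int, int, int] = (2, 2, 2),
    pad_mm: float = 4.0,
) -> ImageVolume:
    """Static PET activity volume for one tracer.

    Activity = habitat SUV x injected_dose / body_weight, blurred by a
    Gaussian point-spread function of ``psf_fwhm`` (mm) and stored on a
    finer grid than the MRI (default 2x per axis) to exercise the
    reframing/down-sampling path.  The PET field of view extends ``pad_mm``
    beyond the MRI slab on every side (PET/CT covers more than the MRI
    imaging slab), so misaligned objects stay inside the volume.
    """
    if cfg.injected_dose <= 0 or cfg.body_weight <= 0:
        raise ValueError("injected_dose and body_weight must be positive")
    tracer = tracer.upper()
    if tracer not in ("FDG", "FLT"):
        raise ValueError("tracer must be FDG or FLT")
    suv = truth.parameter_map("suv_fdg" if tracer == "FDG" else "suv_flt")
    activity = suv * (cfg.injected_dose / cfg.body_weight)
    fine = np.kron(activity, np.ones(upsample))
    up = np.asarray(upsample, float)
    affine = truth.affine.copy()
    affine[:3, :3] = affine[:3, :3] / up
    # keep voxel-center correspondence: fine voxel 0 center sits a half fine
    # voxel in from the coarse voxel 0 center
    shift = truth.affine[:3, :3] @ ((1.0 / up - 1.0) / 2.0)
    affine[:3, 3] = truth.affine[:3, 3] + shift
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if pad_mm > 0:
        pad_vox = np.ceil(pad_mm / spacing).astype(int)
        fine = np.pad(fine, [(p, p) for p in pad_vox])
        affine[:3, 3] = affine[:3, 3] - affine[:3, :3] @ pad_vox
    if psf_fwhm > 0:
        sigma_vox = (psf_fwhm / 2.354820045) / spacing
        fine = ndi.gaussian_filter(fine, sigma_vox)
    if cfg.pet_noise_sd > 0:
        rng = np.random.default_rng(seed)
        fine = fine + rng.normal(0.0, cfg.pet_noise_sd, fine.shape)
    return ImageVolume(fine, affine)


# Monotone maps from habitat imaging parameters to stain Poisson rates
# (counts per histology pixel): dense tissue (low ADC) -> more nuclei,
# permeable vasculature (high Ktrans) -> more vessels, proliferation tracks
# FLT uptake, glucose transporter expression tracks FDG uptake, and hypoxia
# (pimonidazole) tracks high metabolism with poor vascular supply.
def _stain_rates(par: HabitatParams) -> dict[str, float]:
    return {
        "hne_nuclei": 8.0e-3 / par.adc,
        "cd31_vessels": 2.0 + 20.0 * par.ktrans,
        "ki67_nuclei": 4.0 * par.suv_flt,
        "glut1_area": 5.0 * par.suv_fdg,
        "pimonidazole": 20.0 * par.suv_fdg * float(np.exp(-par.ktrans / 0.15)),
    }


def simulate_histology(
    truth: PhantomTruth,
    section_index: int | None = None,
    px_per_voxel: int = 4,
    seed: int = 0,
    rate_override: dict[int, dict[str, float]] | None = None,
):
    """Matched 2D stain-density section drawn from habitat Poisson rates.

    Returns a :class:`habitatpipe.histology.StainDensitySection` whose pixel
    grid refines the chosen axial slice of the phantom by ``px_per_voxel``
    per in-plane axis.  Necrotic and background pixels are invalid (they
    emulate the excluded non-living tissue).
    """
    from .histology import StainDensitySection

    if section_index is None:
        section_index = truth.labels.shape[2] // 2
    slab = truth.labels[:, :, section_index]
    if not (slab != 0).any():
        raise ValueError(f"section {section_index} does not intersect the tumor")
    rng = np.random.default_rng(seed)
    up = np.ones((px_per_voxel, px_per_voxel))
    labels2d = np.kron(slab, up).astype(int)
    valid = labels2d > 0
    maps = {}
    for stain in ("hne_nuclei", "cd31_vessels", "ki67_nuclei", "glut1_area",
                  "pimonidazole"):
        rate = np.zeros_like(labels2d, dtype=float)
        for lab, par in truth.habitat_params.items():
            r = _stain_rates(par)[stain]
            if rate_override and lab in rate_override:
                r = rate_override[lab].get(stain, r)
            rate[labels2d == lab] = r
        maps[stain] = rng.poisson(rate).astype(float)
    px_um = truth.grid_spacing[0] * 1000.0 / px_per_voxel
    return StainDensitySection(
        maps=maps, valid=valid, pixel_size_um=px_um,
        truth_labels=labels2d,
    )


def apply_misalignment(vol: ImageVolume, affine12: np.ndarray,
                       order: int = 1) -> ImageVolume:
    """Resample ``vol`` as if the subject pose differed by ``affine12``.

    ``affine12`` is a 4x4 world-space (RAS, mm) transform A; the output
    volume keeps the original grid but holds ``data(A^-1 x)``, i.e. the
    object appears moved by A.  Registration should therefore recover A.
    """
    a = np.asarray(affine12, dtype=float)
    if a.shape != (4, 4) or abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("affine12 must be an invertible 4x4 matrix")
    vox = vol.affine
    m = np.linalg.inv(vox) @ np.linalg.inv(a) @ vox
    out = ndi.affine_transform(
        vol.data.astype(float), m[:3, :3], offset=m[:3, 3], order=order,
        mode="constant", cval=0.0,
    )
    return ImageVolume(out, vol.affine.copy(), vol.frame_times)


def misaligned_tumor_mask(truth: PhantomTruth, grid_like: ImageVolume,
                          affine12: np.ndarray) -> ImageVolume:
    """Tumor mask as seen by a misaligned acquisition on ``grid_like``'s grid.

    The mask (float, 0..1 after interpolation) represents the tumor moved by
    the world transform ``affine12`` and sampled on the target grid — the
    ground-truth companion of :func:`apply_misalignment` for Dice scoring.
    """
    m = (np.linalg.inv(truth.affine) @ np.linalg.inv(np.asarray(affine12))
         @ grid_like.affine)
    out = ndi.affine_transform(
        truth.tumor_mask.astype(float), m[:3, :3], offset=m[:3, 3],
        output_shape=grid_like.data.shape[:3], order=1,
        mode="constant", cval=0.0,
    )
    return ImageVolume(out, grid_like.affine.copy())


def random_rigid_affine(
    rng: np.random.Generator,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 5.0,
    center_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Small random rigid world transform (rotation about ``center_mm``)."""
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    r = rz @ ry @ rx
    a = np.eye(4)
    a[:3, :3] = r
    c = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
    a[:3, 3] = t + c - r @ c
    return a


def sample_feature_cohort(
    n_subjects: int = 4,
    n_timepoints: int = 2,
    n_habitats: int = 5,
    separation: float = 3.0,
    grid_dims: tuple[int, int, int] = (48, 48, 8),
    necrotic_fraction: float = 0.37,
    seed: int = 0,
):
    """Pooled voxel feature table for a phantom cohort, with truth labels.

    Emulates the pooled five-feature matrix after mapping and registration:
    each subject-timepoint gets its own habitat geometry (different seeds,
    hence different compositions) and every viable voxel receives its
    habitat's feature vector plus isotropic Gaussian noise calibrated in
    pooled z-score space so that every habitat pair differs by at least
    ``separation`` noise SDs in its most discriminative feature (the usual
    planted-partition notion of "separated by s SD").

    Returns ``(features_df, truth_labels)`` where ``features_df`` carries
    provenance columns (subject, timepoint, i, j, k) plus the five features.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    table = DEFAULT_HABITAT_TABLE[:n_habitats]
    cent = np.array([p.features() for p in table])
    fsd = cent.std(axis=0, ddof=0)
    z = (cent - cent.mean(axis=0)) / fsd
    dmin = min(
        np.abs(z[i] - z[j]).max()
        for i in range(n_habitats)
        for j in range(i + 1, n_habitats)
    )
    sigma_z = dmin / separation
    noise_sd = sigma_z * fsd

    rows = []
    labels_all = []
    for s in range(n_subjects):
        for tp in range(n_timepoints):
            truth = generate_phantom(
                grid_dims=grid_dims, n_habitats=n_habitats,
                necrotic_fraction=necrotic_fraction,
                seed=int(rng.integers(2**31 - 1)),
            )
            idx = np.argwhere(truth.viable_mask)
            labs = truth.labels[tuple(idx.T)]
            feats = cent[labs - 1] + rng.normal(0.0, noise_sd, (len(labs), 5))
            df = pd.DataFrame(feats, columns=list(FEATURES))
            df.insert(0, "subject", f"s{s:02d}")
            df.insert(1, "timepoint", tp)
            df[["i", "j", "k"]] = idx
            rows.append(df)
            labels_all.append(labs)
    return pd.concat(rows, ignore_index=True), np.concatenate(labels_all)
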