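"""Histology habitat analysis from stain density sections.

Inputs are per-stain cell-detection density maps (H&E nuclei, CD31 vessels,
Ki67+ nuclei, GLUT1+ area, pimonidazole+ density) on a common pixel grid
with a living-tissue validity mask.  Maps are smoothed with a uniform box
kernel, bilinearly resampled to a coarser analysis resolution, pooled
across sections, z-scored and clustered with the same Ward-linkage core
used for imaging habitats.  Pimonidazole is withheld from clustering and
used to validate hypoxia localisation by colocalization shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.transform import resize

from .habitats import FeatureMatrix, HabitatClustering, HabitatModel

__all__ = [
    "StainDensitySection",
    "CLUSTER_STAINS",
    "section_from_cell_table",
    "read_section_images",
    "density_features",
    "cluster_histology",
    "hypoxia_colocalization",
]

# stains used as clustering features; pimonidazole is validation-only
CLUSTER_STAINS = ("hne_nuclei", "cd31_vessels", "ki67_nuclei", "glut1_area")


@dataclass
class StainDensitySection:
    """Per-stain 2D density maps with a living-tissue validity mask."""

    maps: dict[str, np.ndarray]
    valid: np.ndarray
    pixel_size_um: float
    truth_labels: np.ndarray | None = None  # phantom ground truth, if any

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()} | {self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("all stain maps must share the grid")


@dataclass
class HistologyHabitatMap:
    """Histology cluster label map per section plus composition."""

    labels: np.ndarray  # 0 where invalid
    section_id: object = None


def section_from_cell_table(
    table: pd.DataFrame,
    pixel_size_um: float,
    shape: tuple[int, int] | None = None,
    valid: np.ndarray | None = None,
) -> StainDensitySection:
    """Build a density section from a cell-detection table.

    ``table`` needs columns ``x``, ``y`` (micrometres) and ``class`` (one of
    the stain names); detections are binned onto a ``pixel_size_um`` grid to
    give per-pixel counts per stain.  ``valid`` defaults to all-true.
    """
    for col in ("x", "y", "class"):
        if col not in table.columns:
            raise ValueError(f"cell table needs column '{col}'")
    xi = (table["x"].to_numpy(float) / pixel_size_um).astype(int)
    yi = (table["y"].to_numpy(float) / pixel_size_um).astype(int)
    if shape is None:
        shape = (int(xi.max()) + 1, int(yi.max()) + 1)
    maps = {}
    for stain in table["class"].unique():
        sel = (table["class"] == stain).to_numpy()
        counts = np.zeros(shape)
        np.add.at(counts, (np.clip(xi[sel], 0, shape[0] - 1),
                           np.clip(yi[sel], 0, shape[1] - 1)), 1.0)
        maps[str(stain)] = counts
    if valid is None:
        valid = np.ones(shape, bool)
    return StainDensitySection(maps=maps, valid=valid,
                               pixel_size_um=pixel_size_um)


def read_section_images(paths: dict[str, str], pixel_size_um: float,
                        valid_path: str | None = None) -> StainDensitySection:
    """Load per-stain density images (TIFF/PNG) as a section.

    ``paths`` maps stain name to image file; an optional ``valid_path``
    image marks living tissue (nonzero = valid).
    """
    import imageio.v3 as iio

    maps = {stain: np.asarray(iio.imread(p), dtype=float)
            for stain, p in paths.items()}
    valid = None
    if valid_path is not None:
        valid = np.asarray(iio.imread(valid_path)) > 0
    else:
        valid = np.ones(next(iter(maps.values())).shape, bool)
    return StainDensitySection(maps=maps, valid=valid,
                               pixel_size_um=pixel_size_um)


def density_features(
    section: StainDensitySection,
    kernel_px: int = 10,
    target_px_um: float = 100.0,
) -> StainDensitySection:
    """Box-smooth and bilinearly down-sample stain maps to analysis resolution.

    Smoothing uses a uniform ``kernel_px`` x ``kernel_px`` box kernel (zero
    padding, so the raw smoothed map conserves the global sum exactly).
    Near the living-tissue boundary the density is corrected by the valid
    footprint fraction (normalized convolution), and pixels whose kernel
    footprint is mostly outside living tissue are dropped from the eroded
    validity mask.  Down-sampling targets ``target_px_um`` per pixel.
    """
    if kernel_px < 1:
        raise ValueError("kernel_px must be >= 1")
    factor = target_px_um / section.pixel_size_um
    if factor < 1.0:
        factor = 1.0
    out_shape = tuple(
        max(1, int(round(s / factor))) for s in section.valid.shape
    )
    vfrac_full = ndi.uniform_filter(section.valid.astype(float),
                                    size=kernel_px, mode="constant")
    maps = {}
    for stain, m in section.maps.items():
        sm = ndi.uniform_filter(m.astype(float), size=kernel_px, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(vfrac_full > 0.05, sm / np.maximum(vfrac_full, 0.05),
                          0.0)
        maps[stain] = resize(sm, out_shape, order=1, mode="edge",
                             anti_aliasing=False)
    valid = resize(vfrac_full, out_shape, order=1, mode="edge",
                   anti_aliasing=False) > 0.6
    truth = None
    if section.truth_labels is not None:
        truth = resize(section.truth_labels.astype(float), out_shape, order=0,
                       mode="edge", anti_aliasing=False).astype(int)
    return StainDensitySection(
        maps=maps, valid=valid,
        pixel_size_um=section.pixel_size_um * factor,
        truth_labels=truth,
    )


def cluster_histology(
    sections: dict[object, StainDensitySection],
    k: int | None = None,
    k_range=range(2, 9),
    stains=CLUSTER_STAINS,
    seed: int = 0,
) -> tuple[HabitatModel, dict[object, HistologyHabitatMap]]:
    """Pool valid pixels across sections and cluster into histology habitats.

    Features are the four clustering stains (pimonidazole withheld for
    validation), z-scored over the pooled table and clustered by the shared
    Ward-linkage core; labels are remapped onto each section grid.
    Returns the fitted model and per-section label maps.
    """
    rows = []
    shapes = {}
    for sid, sec in sections.items():
        idx = np.argwhere(sec.valid)
        if len(idx) == 0:
            continue
        feats = np.stack([sec.maps[s][sec.valid] for s in stains], axis=1)
        df = pd.DataFrame(feats, columns=list(stains))
        df.insert(0, "subject", sid)
        df.insert(1, "timepoint", 0)
        df["i"] = idx[:, 0]
        df["j"] = idx[:, 1]
        df["k"] = 0
        rows.append(df)
        shapes[(sid, 0)] = (*sec.valid.shape, 1)
    if not rows:
        raise ValueError("no valid histology pixels to cluster")
    fm = FeatureMatrix.from_dataframe(
        pd.concat(rows, ignore_index=True), feature_names=stains,
        grid_shapes=shapes,
    )
    model = HabitatClustering(fm).fit(k=k, k_range=k_range, seed=seed)
    maps = {}
    for sid in sections:
        if (sid, 0) not in shapes:
            continue
        lab3 = _remap_2d(model, sid)
        maps[sid] = HistologyHabitatMap(labels=lab3, section_id=sid)
    return model, maps


def _remap_2d(model: HabitatModel, sid) -> np.ndarray:
    from .habitats import remap

    lab3 = remap(model, sid, 0)
    return lab3[:, :, 0]


def histology_composition(model: HabitatModel) -> pd.DataFrame:
    """Percent of valid pixels per habitat and section (rows sum to 100)."""
    from .habitats import composition

    comp = composition(model)
    comp.index = comp.index.droplevel("timepoint")
    return comp


def hypoxia_colocalization(
    habitat_map: HistologyHabitatMap | np.ndarray,
    pimo: np.ndarray,
) -> dict[int, float]:
    """Per-habitat share of the total pimonidazole-positive density.

    Shares are computed over valid (labelled) pixels and sum to 1.
    """
    labels = (habitat_map.labels if isinstance(habitat_map, HistologyHabitatMap)
              else np.asarray(habitat_map))
    pimo = np.asarray(pimo, dtype=float)
    if labels.shape != pimo.shape:
        raise ValueError("habitat map and pimonidazole map must share the grid")
    mask = labels > 0
    total = float(pimo[mask].sum())
    if total <= 0:
        raise ValueError("no pimonidazole-positive density in labelled tissue")
    return {
        int(h): float(pimo[labels == h].sum()) / total
        for h in np.unique(labels[mask])
    }
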