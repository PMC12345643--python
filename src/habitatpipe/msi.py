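"""Multiregional spatial interaction (MSI) statistics for habitat maps.

Spatial contiguity of habitat labels is quantified as the fraction of all
neighbouring voxel pairs (3D face or full-neighbourhood connectivity)
falling on each unordered label pair.  The observed fractions are compared
against a size-preserving randomised null — labels shuffled uniformly over
the labelled voxel positions, so every habitat keeps its volume — via
per-pair z-scores.  Large positive diagonal z indicates habitats that are
spatially coherent rather than randomly dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MSIMatrix", "count_pairs", "randomized_null", "msi_zscores"]

_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
# unique half-space of the 26-neighbourhood: 13 offsets
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


@dataclass
class MSIMatrix:
    """k x k neighbour-pair fractions with optional null statistics.

    ``pair_fraction`` is symmetric; its entries over unique unordered pairs
    (upper triangle including diagonal) sum to 1.
    """

    pair_fraction: np.ndarray
    labels: np.ndarray  # the habitat ids the matrix rows refer to
    connectivity: int
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    z: np.ndarray | None = None
    n_randomizations: int = 0

    @property
    def diagonal_z(self) -> np.ndarray:
        if self.z is None:
            raise ValueError("z-scores not computed")
        return np.diag(self.z)


def _neighbor_offsets(connectivity: int):
    if connectivity == 6:
        return _OFFSETS_6
    if connectivity == 26:
        return _OFFSETS_26
    raise ValueError("connectivity must be 6 or 26")


def _edges(labels: np.ndarray, connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the flat labelled-voxel list) of neighbouring pairs."""
    lab = np.asarray(labels)
    pos = lab > 0
    index = -np.ones(lab.shape, dtype=np.int64)
    index[pos] = np.arange(int(pos.sum()))
    e_a, e_b = [], []
    for off in _neighbor_offsets(connectivity):
        sl_a = tuple(slice(max(0, -o), n - max(0, o))
                     for o, n in zip(off, lab.shape))
        sl_b = tuple(slice(max(0, o), n - max(0, -o))
                     for o, n in zip(off, lab.shape))
        a = index[sl_a]
        b = index[sl_b]
        ok = (a >= 0) & (b >= 0)
        e_a.append(a[ok])
        e_b.append(b[ok])
    return np.concatenate(e_a), np.concatenate(e_b)


def _fractions_from_edges(flat_labels: np.ndarray, e_a: np.ndarray,
                          e_b: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    k = len(uniq)
    lut = np.zeros(int(uniq.max()) + 1, dtype=np.int64)
    lut[uniq] = np.arange(k)
    la = lut[flat_labels[e_a]]
    lb = lut[flat_labels[e_b]]
    lo = np.minimum(la, lb)
    hi = np.maximum(la, lb)
    counts = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k).astype(float)
    frac = counts / counts.sum()
    return frac + np.triu(frac, 1).T  # symmetrise (upper triangle holds all mass)


def count_pairs(labels: np.ndarray, connectivity: int = 6) -> MSIMatrix:
    """Neighbour-pair fractions among labelled (> 0) voxels.

    Counts unordered neighbouring pairs where both voxels carry a positive
    habitat label, normalised by the total number of such pairs.
    """
    lab = np.asarray(labels)
    if int((lab > 0).sum()) < 2:
        raise ValueError("need at least two labelled voxels")
    e_a, e_b = _edges(lab, connectivity)
    if len(e_a) == 0:
        raise ValueError("no neighbouring labelled voxel pairs")
    uniq = np.unique(lab[lab > 0])
    flat = lab[lab > 0]
    frac = _fractions_from_edges(flat, e_a, e_b, uniq)
    return MSIMatrix(pair_fraction=frac, labels=uniq, connectivity=connectivity)


def randomized_null(
    labels: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Null pair-fraction mean/SD from size-preserving label shuffles.

    Labels are permuted uniformly over the labelled voxel positions ``n``
    times (each habitat keeps its voxel count; only locations change) and
    the per-pair-type fraction mean and SD are returned.
    """
    if n < 100:
        raise ValueError("need at least 100 randomizations")
    lab = np.asarray(labels)
    e_a, e_b = _edges(lab, connectivity)
    uniq = np.unique(lab[lab > 0])
    flat = lab[lab > 0]
    rng = np.random.default_rng(seed)
    k = len(uniq)
    acc = np.zeros((n, k, k))
    for r in range(n):
        perm = rng.permutation(flat)
        acc[r] = _fractions_from_edges(perm, e_a, e_b, uniq)
    return acc.mean(axis=0), acc.std(axis=0, ddof=0)


def msi_zscores(observed: MSIMatrix, null_mean: np.ndarray,
                null_sd: np.ndarray) -> MSIMatrix:
    """Attach ``z = (observed - null_mean) / null_sd`` (NaN where SD = 0)."""
    if observed.pair_fraction.shape != null_mean.shape:
        raise ValueError("shape mismatch between observed and null matrices")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0,
                     (observed.pair_fraction - null_mean) / null_sd, np.nan)
    observed.null_mean = null_mean
    observed.null_sd = null_sd
    observed.z = z
    return observed


def expected_null_self_fraction(labels: np.ndarray, habitat: int) -> float:
    """Analytic null expectation of a habitat's self-pair fraction.

    Under uniform label permutation each edge is a self-pair of habitat h
    with probability ``n_h (n_h - 1) / (N (N - 1))`` — independent of the
    edge structure.
    """
    lab = np.asarray(labels)
    flat = lab[lab > 0]
    n_total = len(flat)
    n_h = int((flat == habitat).sum())
    return n_h * (n_h - 1) / (n_total * (n_total - 1))
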