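"""Tumor habitat discovery by pooled hierarchical clustering.

Voxel-wise features (ADC, Ktrans, ve, FDG-SUV, FLT-SUV) from all subjects
and timepoints are pooled into one matrix, filtered to physiologically
plausible ranges, z-scored feature-wise, and clustered with Ward-linkage
agglomerative clustering.  The cluster count is selected by mean silhouette
over a candidate range (default 2-8).  Clusters ("habitats") are
characterised by flagging each feature high/low against the cross-cluster
median of centroids and named from a configurable signature table seeded
with the five reference phenotypes: high vascularity (HV), hypoxic
responding (HRSP), transitional zone (TZ), active tumor (ATMR) and
responding (RSP).  Longitudinal composition tables and spatial remapping
close the loop back to image space.

``vp`` is fitted upstream but deliberately not clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .mapping import ADCMap, SUVMap, ToftsMap

__all__ = [
    "FEATURES",
    "DEFAULT_RANGES",
    "DEFAULT_NAMING_RULES",
    "ParametricMapSet",
    "FeatureMatrix",
    "HabitatModel",
    "assemble_features",
    "normalize",
    "cluster",
    "select_k",
    "characterize",
    "composition",
    "remap",
]

FEATURES = ("adc", "ktrans", "ve", "suv_fdg", "suv_flt")
PROVENANCE = ("subject", "timepoint", "i", "j", "k")

# Physiological plausibility ranges for pooled features; lower bounds of
# zero are exclusive (a zero value is physically meaningless there).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "adc": (0.1e-3, 3.0e-3),
    "ktrans": (0.0, 5.0),
    "ve": (0.0, 1.0),
    "suv_fdg": (0.0, 20.0),
    "suv_flt": (0.0, 20.0),
}

# Signature -> habitat name table (data, not code: override via config).
# Rules are applied in order; each assigns its name to the first unnamed
# cluster matching every stated high/low constraint.
DEFAULT_NAMING_RULES: tuple[dict, ...] = (
    {"name": "RSP", "requires": {"adc": "low", "ktrans": "low", "ve": "low",
                                 "suv_fdg": "low", "suv_flt": "low"}},
    {"name": "HRSP", "requires": {"ktrans": "low", "ve": "high",
                                  "suv_fdg": "low"}},
    {"name": "HV", "requires": {"ktrans": "high", "ve": "high"}},
    {"name": "ATMR", "requires": {"suv_fdg": "high", "suv_flt": "high",
                                  "ktrans": "low"}},
    {"name": "TZ", "requires": {"adc": "high"}},
)


@dataclass
class ParametricMapSet:
    """All per-voxel maps of one subject-timepoint on a common grid."""

    adc: ADCMap
    tofts: ToftsMap
    suv_fdg: SUVMap
    suv_flt: SUVMap

    def feature_stack(self) -> np.ndarray:
        return np.stack(
            [self.adc.adc, self.tofts.ktrans, self.tofts.ve,
             self.suv_fdg.suv, self.suv_flt.suv], axis=-1)

    def valid_mask(self) -> np.ndarray:
        return self.adc.valid & self.tofts.valid


@dataclass
class FeatureMatrix:
    """Pooled voxel-by-feature table with provenance and normalisation state.

    ``df`` holds the provenance columns (subject, timepoint, i, j, k) plus
    one column per feature.  ``normalization`` maps feature name to the
    (mean, sd) used for z-scoring; None while un-normalised.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURES
    normalization: dict[str, tuple[float, float]] | None = None
    grid_shapes: dict[tuple, tuple[int, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.feature_names)].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_names=FEATURES,
                       grid_shapes=None) -> "FeatureMatrix":
        return cls(df=df.reset_index(drop=True),
                   feature_names=tuple(feature_names),
                   grid_shapes=dict(grid_shapes or {}))


@dataclass
class HabitatModel:
    """Fitted habitat clustering: assignments, centroids, signatures, names."""

    k: int
    assignments: np.ndarray  # cluster id (1..k) per FeatureMatrix row
    centroids: pd.DataFrame  # k rows, original feature units
    fm: FeatureMatrix
    signatures: pd.DataFrame | None = None  # bool: feature high per cluster
    names: dict[int, str] | None = None

    def summary(self) -> str:
        lines = [f"HabitatModel: k={self.k}, n={len(self.fm)} voxels"]
        table = self.centroids.copy()
        if self.names:
            table.insert(0, "name", [self.names.get(c, f"habitat-{c}")
                                     for c in table.index])
        sizes = pd.Series(self.assignments).value_counts().sort_index()
        table["n_voxels"] = sizes.values
        lines.append(table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _in_range(x: np.ndarray, name: str, lo: float, hi: float) -> np.ndarray:
    low_ok = x > lo if lo == 0.0 else x >= lo
    return low_ok & (x <= hi)


def assemble_features(
    maps: dict[tuple, ParametricMapSet],
    tumors: dict[tuple, np.ndarray],
    ranges: dict[str, tuple[float, float]] | None = None,
) -> FeatureMatrix:
    """Pool tumor voxels valid in all five maps and inside the ranges.

    ``maps`` and ``tumors`` are keyed by (subject, timepoint).  Rows keep
    full provenance so habitat labels can be remapped to image space.
    Raises a pipeline error naming the dominant filter if nothing survives.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    rows = []
    shapes = {}
    drop_counts: dict[str, int] = {"validity": 0, **{f: 0 for f in ranges}}
    for key, mset in maps.items():
        tumor = np.asarray(tumors[key], bool)
        shapes[key] = tumor.shape
        stack = mset.feature_stack()
        valid = mset.valid_mask() & tumor & np.all(np.isfinite(stack), axis=-1)
        drop_counts["validity"] += int(tumor.sum() - valid.sum())
        keep = valid.copy()
        with np.errstate(invalid="ignore"):
            for fi, fname in enumerate(FEATURES):
                lo, hi = ranges[fname]
                ok = _in_range(stack[..., fi], fname, lo, hi)
                drop_counts[fname] += int((keep & ~ok).sum())
                keep &= ok
        idx = np.argwhere(keep)
        if len(idx) == 0:
            continue
        df = pd.DataFrame(stack[keep], columns=list(FEATURES))
        subject, timepoint = key
        df.insert(0, "subject", subject)
        df.insert(1, "timepoint", timepoint)
        df[["i", "j", "k"]] = idx
        rows.append(df)
    if not rows:
        dominant = max(drop_counts, key=drop_counts.get)
        raise ValueError(
            f"no voxels survived feature assembly; dominant filter: {dominant} "
            f"(drop counts: {drop_counts})"
        )
    out = pd.concat(rows, ignore_index=True)
    return FeatureMatrix(df=out, grid_shapes=shapes)


def normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each feature over the pooled matrix (all subjects together)."""
    if len(fm) < 2:
        raise ValueError("need at least 2 rows to normalise")
    df = fm.df.copy()
    stats = {}
    for f in fm.feature_names:
        col = df[f].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=0))
        if sd == 0:
            raise ValueError(f"degenerate feature with zero variance: {f}")
        df[f] = (col - mu) / sd
        stats[f] = (mu, sd)
    return FeatureMatrix(df=df, feature_names=fm.feature_names,
                         normalization=stats, grid_shapes=dict(fm.grid_shapes))


def _original_units(fm: FeatureMatrix, X: np.ndarray) -> np.ndarray:
    if fm.normalization is None:
        return X
    out = X.copy()
    for fi, f in enumerate(fm.feature_names):
        mu, sd = fm.normalization[f]
        out[:, fi] = out[:, fi] * sd + mu
    return out


# Ward agglomeration is O(n^2); beyond this row count the tree is built on
# a fixed-seed subsample and remaining voxels join the nearest cluster
# centroid (in z-scored feature space).
MAX_TREE_ROWS = 12_000


def _ward_assign(X: np.ndarray, k: int, max_tree_rows: int = MAX_TREE_ROWS,
                 seed: int = 0,
                 tree: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> np.ndarray:
    """Ward/Euclidean cluster labels (0..k-1) for all rows of ``X``."""
    if tree is None:
        tree = _ward_tree(X, max_tree_rows, seed)
    sub, Z = tree
    labels_sub = fcluster(Z, t=k, criterion="maxclust") - 1
    labels = np.empty(len(X), dtype=int)
    labels[sub] = labels_sub
    rest = np.setdiff1d(np.arange(len(X)), sub, assume_unique=False)
    if len(rest):
        cent = np.stack([X[sub][labels_sub == c].mean(axis=0)
                         for c in range(k)])
        d = ((X[rest][:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        labels[rest] = d.argmin(axis=1)
    return labels


def _ward_tree(X: np.ndarray, max_tree_rows: int, seed: int):
    n = len(X)
    if n > max_tree_rows:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(n, size=max_tree_rows, replace=False))
    else:
        sub = np.arange(n)
    Z = linkage(X[sub], method="ward")
    return sub, Z


def cluster(fm: FeatureMatrix, k: int, max_tree_rows: int = MAX_TREE_ROWS,
            seed: int = 0) -> HabitatModel:
    """Ward-linkage agglomerative clustering into ``k`` habitats.

    Operates on the z-scored features (normalising first if needed);
    deterministic given the input order.  Cluster ids are relabelled 1..k
    by decreasing size for stable reporting; centroids are reported in
    original feature units.
    """
    if k < 1 or k > len(fm):
        raise ValueError(f"k={k} out of range for {len(fm)} rows")
    if fm.normalization is None and k > 1:
        fm = normalize(fm)
    X = fm.X
    if k == 1:
        raw = np.zeros(len(fm), dtype=int)
    else:
        raw = _ward_assign(X, k, max_tree_rows, seed)
    order = np.argsort([-np.sum(raw == c) for c in range(k)], kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    assignments = np.array([relabel[int(c)] for c in raw])
    cent = np.stack([X[assignments == c].mean(axis=0) for c in range(1, k + 1)])
    cent = _original_units(fm, cent)
    centroids = pd.DataFrame(cent, index=range(1, k + 1),
                             columns=list(fm.feature_names))
    centroids.index.name = "habitat"
    return HabitatModel(k=k, assignments=assignments, centroids=centroids, fm=fm)


def select_k(
    fm: FeatureMatrix,
    k_range=range(2, 9),
    max_rows: int = 4000,
    max_tree_rows: int = MAX_TREE_ROWS,
    seed: int = 0,
) -> int:
    """Cluster count maximising the mean silhouette score over ``k_range``.

    The Ward tree is built once and cut at every candidate k; the silhouette
    is evaluated on a fixed-seed subsample of at most ``max_rows`` rows for
    tractability (the score is O(n^2)).  Exact ties resolve to the smaller k.
    """
    ks = [int(k) for k in k_range]
    if min(ks) < 2 or max(ks) > len(fm) - 1:
        raise ValueError("k_range must lie within [2, n_rows - 1]")
    if fm.normalization is None:
        fm = normalize(fm)
    X = fm.X
    rng = np.random.default_rng(seed)
    if len(X) > max_rows:
        sub = rng.choice(len(X), size=max_rows, replace=False)
    else:
        sub = np.arange(len(X))
    tree = _ward_tree(X, max_tree_rows, seed)
    best_k, best_score = ks[0], -np.inf
    for k in ks:
        labels = _ward_assign(X, k, tree=tree)
        score = silhouette_score(X[sub], labels[sub])
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def characterize(model: HabitatModel, naming_rules=DEFAULT_NAMING_RULES) -> HabitatModel:
    """Flag each feature high/low per cluster and assign habitat names.

    The cut for each feature is the median of the k cluster-centroid values;
    a cluster is "high" strictly above the cut.  Names come from the first
    matching signature rule (each name used at most once); clusters with no
    matching rule get generic ``habitat-<id>`` names.
    """
    cent = model.centroids
    cuts = cent.median(axis=0)
    sig = cent.gt(cuts, axis=1)
    names: dict[int, str] = {}
    for rule in naming_rules:
        if not set(rule["requires"]) <= set(sig.columns):
            continue  # rule refers to features absent from this matrix
        for cid in sig.index:
            if cid in names:
                continue
            match = all(
                bool(sig.loc[cid, f]) == (want == "high")
                for f, want in rule["requires"].items()
            )
            if match:
                names[cid] = rule["name"]
                break
    for cid in sig.index:
        names.setdefault(cid, f"habitat-{cid}")
    model.signatures = sig
    model.names = names
    return model


def composition(model: HabitatModel) -> pd.DataFrame:
    """Percent of each subject-timepoint's valid voxels per habitat.

    Returns a table indexed by (subject, timepoint) with one column per
    habitat id; rows sum to 100.
    """
    df = model.fm.df[["subject", "timepoint"]].copy()
    df["habitat"] = model.assignments
    counts = (
        df.groupby(["subject", "timepoint", "habitat"]).size()
        .unstack("habitat", fill_value=0)
        .reindex(columns=range(1, model.k + 1), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def remap(model: HabitatModel, subject, timepoint,
          grid_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Habitat label volume for one subject-timepoint (0 = excluded voxel)."""
    key = (subject, timepoint)
    if grid_shape is None:
        if key not in model.fm.grid_shapes:
            raise KeyError(f"no grid shape recorded for {key}")
        grid_shape = model.fm.grid_shapes[key]
    sel = (model.fm.df["subject"] == subject) & (model.fm.df["timepoint"] == timepoint)
    rows = model.fm.df.loc[sel, ["i", "j", "k"]].to_numpy(dtype=int)
    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[rows[:, 0], rows[:, 1], rows[:, 2]] = model.assignments[sel.to_numpy()]
    return labels


class HabitatClustering:
    """Estimator-style front end: build from a feature table, then fit.

    ``HabitatClustering(fm).fit(k=None, k_range=range(2, 9))`` normalises,
    selects k by silhouette when not given, clusters, and characterises —
    returning the fitted :class:`HabitatModel`.
    """

    def __init__(self, fm: FeatureMatrix, naming_rules=DEFAULT_NAMING_RULES):
        self.fm = fm
        self.naming_rules = naming_rules

    def fit(self, k: int | None = None, k_range=range(2, 9),
            seed: int = 0) -> HabitatModel:
        fm = self.fm
        if k != 1 and fm.normalization is None:
            fm = normalize(fm)
        if k is None:
            k = select_k(fm, k_range=k_range, seed=seed)
        model = cluster(fm, k)
        return characterize(model, self.naming_rules)
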