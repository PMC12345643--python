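"""Validation statistics: habitat matching and group comparisons.

Histology-derived habitats carry arbitrary cluster ids; they are matched to
imaging habitats by exhaustively permuting cluster composition percentages
and keeping the bijection with the highest summed Pearson correlation
across habitats.  The module also provides the central-slice selector (best
correlation within a five-slice window), Pearson correlations with
t-distribution p-values, an exact-enumeration Mann-Whitney U test for small
groups, and one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "MatchResult",
    "select_central_slice",
    "match_by_permutation",
    "correlate_compositions",
    "compare_groups",
    "anova_tukey",
]


@dataclass
class MatchResult:
    """Histology-to-imaging habitat matching with per-habitat correlations."""

    permutation: dict[int, int]  # imaging habitat id -> histology cluster id
    r: dict[int, float] = field(default_factory=dict)
    r2: dict[int, float] = field(default_factory=dict)
    p: dict[int, float] = field(default_factory=dict)
    objective: float = 0.0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def select_central_slice(
    imaging_percent_by_slice,
    histology_percent,
    slice_ids=None,
) -> int:
    """Slice (within the candidate window) best matching histology.

    ``imaging_percent_by_slice`` is an (n_slices, k) array of per-slice
    habitat percentages; the returned slice maximises the Pearson
    correlation with the histology percentage vector.  Ties resolve to the
    slice nearest the window center.
    """
    window = np.atleast_2d(np.asarray(imaging_percent_by_slice, float))
    hist = np.asarray(histology_percent, float)
    n = window.shape[0]
    if n == 0:
        raise ValueError("empty slice window")
    ids = list(range(n)) if slice_ids is None else list(slice_ids)
    rs = np.array([_pearson(window[i], hist) for i in range(n)])
    center = (n - 1) / 2.0
    best = max(range(n), key=lambda i: (rs[i], -abs(i - center)))
    return ids[best]


def match_by_permutation(hist_percent, img_percent, k: int | None = None) -> MatchResult:
    """Exhaustive bijective matching of histology clusters to imaging habitats.

    ``hist_percent`` and ``img_percent`` are (n_subjects, k) arrays of
    composition percentages with columns ordered by cluster id (1..k).  All
    k! bijections are scored by the summed per-habitat Pearson correlation;
    exact ties resolve to the lexicographically smallest permutation.
    """
    hist = np.atleast_2d(np.asarray(hist_percent, float))
    img = np.atleast_2d(np.asarray(img_percent, float))
    if k is None:
        k = img.shape[1]
    if k > 8:
        raise ValueError("exhaustive matching supports k <= 8")
    if hist.shape[1] != k or img.shape[1] != k:
        raise ValueError("composition tables must have k columns")
    best_perm = None
    best_obj = -np.inf
    for perm in itertools.permutations(range(k)):
        obj = sum(_pearson(img[:, h], hist[:, perm[h]]) for h in range(k))
        if obj > best_obj + 1e-12:
            best_obj = obj
            best_perm = perm
    mapping = {h + 1: best_perm[h] + 1 for h in range(k)}
    result = MatchResult(permutation=mapping, objective=float(best_obj))
    n = img.shape[0]
    for h in range(k):
        x, y = img[:, h], hist[:, best_perm[h]]
        r = _pearson(x, y)
        result.r[h + 1] = r
        result.r2[h + 1] = r * r
        result.p[h + 1] = _pearson_p(r, n)
    return result


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n >= 3 else np.nan
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def correlate_compositions(img_values, hist_values) -> dict:
    """Pearson r, R^2 and two-sided t-distribution p for one habitat.

    Requires at least 3 paired subjects.
    """
    x = np.asarray(img_values, float)
    y = np.asarray(hist_values, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    r = _pearson(x, y)
    return {"r": r, "r2": r * r, "p": _pearson_p(r, len(x))}


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of group x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def compare_groups(values_a, values_b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all C(n1+n2, n1) group assignments (correct under
    ties via midranks) when both groups have at most ``exact_max_n``
    observations; normal approximation with tie correction otherwise.
    Returns (U, p).
    """
    x = np.asarray(values_a, float)
    y = np.asarray(values_b, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        base = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - base
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie = (counts**3 - counts).sum() / (n * (n - 1))
        sd = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie))
        if sd == 0:
            return u_obs, 1.0
        z = (abs(u_obs - mu) - 0.5) / sd  # continuity corrected
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return u_obs, float(min(1.0, p))


def anova_tukey(groups) -> dict:
    """One-way ANOVA F test followed by Tukey HSD pairwise comparisons.

    ``groups`` is a sequence of >= 2 samples (each >= 2 observations).
    Returns ``{"F", "p", "tukey": [(i, j, diff, p_adj), ...]}`` with
    adjusted p-values from the studentized range distribution.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if ssb == 0 else np.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / df_b) / msw
        p = float(sps.f.sf(f, df_b, df_w))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            if msw == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(msw / 2.0 * (1 / len(gs[i]) + 1 / len(gs[j])))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append((i, j, float(diff), min(1.0, p_adj)))
    return {"F": float(f), "p": float(p), "tukey": pairs}
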