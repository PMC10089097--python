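"""Cluster-based sign-permutation test of ssPAC maps against zero.

Group-level inference on the 2-D phase x amplitude grid: a one-sample
t map across subjects is thresholded (two-tailed parametric threshold by
default), suprathreshold cells are grouped into connected clusters
(4-connectivity by default) separately for each sign, and each observed
cluster's mass (sum of t values) is compared against the permutation
null of the maximum absolute cluster mass obtained by randomly flipping
the sign of whole subject maps.  Using the single max-|mass| statistic
controls the family-wise error rate across both signs jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sst

from .containers import SsPacMap


@dataclass
class Cluster:
    """One suprathreshold connected component on the grid."""

    cells: list[tuple[int, int]]
    sign: int  # +1 or -1
    mass: float
    p: float = np.nan

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_t: float
    n_perm: int
    alpha: float
    phase_freqs: np.ndarray | None = None
    amp_freqs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    null_max_mass: np.ndarray | None = None  # permutation null of max |cluster mass|

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]


def _stack(maps) -> np.ndarray:
    arrays = [m.values if isinstance(m, SsPacMap) else np.asarray(m, dtype=float) for m in maps]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("all subject maps must share one grid shape")
    if isinstance(maps[0], SsPacMap):
        first = maps[0]
        for m in maps[1:]:
            if not first.same_grid(m):
                raise ValueError("subject maps are on different frequency grids")
    return np.stack(arrays)


def t_map(maps) -> np.ndarray:
    """Per-cell one-sample t across subjects (sd with n-1 denominator).

    Zero-variance cells yield +/-inf (or 0 when the mean is also zero)
    with a warning.
    """
    x = _stack(maps)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subject maps")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd <= np.abs(mean) * 1e-12
    if np.any(degenerate):
        warnings.warn("zero-variance cells in t map; t set to +/-inf", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.sign(mean) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def form_clusters(t: np.ndarray, threshold_t: float, connectivity: int = 4) -> list[Cluster]:
    """Connected components of suprathreshold cells, per sign.

    Positive clusters come from {t > threshold}, negative from
    {t < -threshold}; cells in a cluster share an edge (4-connectivity)
    or an edge/corner (8-connectivity). Mass is the sum of t over cells.
    """
    if not np.isfinite(threshold_t) or threshold_t <= 0:
        raise ValueError("threshold_t must be finite and positive")
    t = np.asarray(t, dtype=float)
    struct = _structure(connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = t > threshold_t if sign == 1 else t < -threshold_t
        labeled, n_lab = ndimage.label(mask, structure=struct)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labeled == lab)
            mass = float(t[labeled == lab].sum())
            clusters.append(Cluster(cells=[tuple(c) for c in idx], sign=sign, mass=mass))
    return clusters


def _max_cluster_mass(t: np.ndarray, threshold_t: float, struct: np.ndarray) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = t > threshold_t if sign == 1 else t < -threshold_t
        if not mask.any():
            continue
        labeled, n_lab = ndimage.label(mask, structure=struct)
        masses = ndimage.sum_labels(t, labeled, index=np.arange(1, n_lab + 1))
        best = max(best, float(np.max(np.abs(masses))))
    return best


def permutation_test(
    maps,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    threshold_t: float | None = None,
    connectivity: int = 4,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of the subject maps vs zero.

    The null distribution is the maximum absolute cluster mass over
    ``n_perm`` random whole-map sign flips; each observed cluster's
    p-value is ``(1 + #{null >= |mass|}) / (n_perm + 1)`` (add-one
    estimator, two-tailed via the shared max statistic) and is declared
    significant when p < alpha.  ``threshold_t`` defaults to the
    parametric two-tailed t quantile at the same alpha.
    """
    x = _stack(maps)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subject maps")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", RuntimeWarning)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if threshold_t is None:
        threshold_t = float(sst.t.ppf(1.0 - alpha / 2.0, n - 1))
    struct = _structure(connectivity)

    grid_shape = x.shape[1:]
    t_obs = t_map(x)
    observed = form_clusters(t_obs, threshold_t, connectivity)

    # Vectorized sign-flip null: for each permutation the flipped mean is
    # signs @ X / n and the flipped variance follows from the invariant
    # sum of squares, so no per-permutation restacking is needed.
    flat = x.reshape(n, -1)
    ss = np.einsum("ij,ij->j", flat, flat)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    means = signs @ flat / n
    var = np.maximum((ss[None, :] - n * means**2) / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n)
    t_null = np.where(np.isnan(t_null), 0.0, t_null)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        null_max[k] = _max_cluster_mass(t_null[k].reshape(grid_shape), threshold_t, struct)

    for cl in observed:
        cl.p = float((1 + np.sum(null_max >= abs(cl.mass) - 1e-12)) / (n_perm + 1))

    first = maps[0] if isinstance(maps[0], SsPacMap) else None
    return ClusterResult(
        clusters=observed,
        t_map=t_obs,
        threshold_t=threshold_t,
        n_perm=n_perm,
        alpha=alpha,
        phase_freqs=None if first is None else first.phase_freqs,
        amp_freqs=None if first is None else first.amp_freqs,
        meta={} if first is None else {k: v for k, v in first.meta.items() if k != "subject_id"},
        null_max_mass=null_max,
    )
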