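"""Voxelwise GLM estimation and permutation-based group inference.

First level: ordinary least squares per voxel against the assembled design
matrix, with effect sizes converted to percent signal change (PSC).  Second
level: weighted least-squares regression of subject PSC maps on an intercept
(the group mean) plus nuisance covariates, with an F-contrast on the
intercept.  Family-wise error is controlled by the permutation max-statistic
method under the Freedman-Lane scheme, with threshold-free cluster
enhancement (TFCE, H = 2, E = 0.5, step = 0.1) applied to every observed and
permuted map, and a cluster-extent filter (20 contiguous voxels) on the
surviving suprathreshold set.

For the intercept (group-mean) contrast the permutation action is
sign-flipping of the nuisance-model residuals — the standard exchangeability
choice for one-sample permutation tests, since row permutation leaves a
one-sample statistic unchanged.  Row permutation is available for covariate
contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "FirstLevelResult",
    "first_level",
    "psc_convert",
    "second_level_wls",
    "tfce",
    "freedman_lane_permute",
    "fwe_correct",
    "cluster_filter",
    "GroupResult",
]

TFCE_H = 2.0
TFCE_E = 0.5
TFCE_STEP = 0.1
MIN_CLUSTER_VOXELS = 20
ALPHA_FWE = 0.05


# --------------------------------------------------------------------------
# first level
# --------------------------------------------------------------------------

@dataclass
class FirstLevelResult:
    betas: np.ndarray            # (p, ...) voxel betas per regressor
    resid_var: np.ndarray        # residual variance map
    dof: int
    columns: list
    baseline_mean: np.ndarray    # mean signal per voxel (PSC denominator)
    shape: tuple                 # spatial shape

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.columns.index(name)]

    def psc(self, name: str, task_column: np.ndarray) -> np.ndarray:
        return psc_convert(self.beta(name), task_column, self.baseline_mean)


def _as_timeseries(bold) -> tuple[np.ndarray, tuple]:
    """Accepts a SyntheticBold, 4-D array (x,y,z,t) or 2-D (t, voxels)."""
    data = getattr(bold, "data", bold)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 4:
        shape = arr.shape[:3]
        Y = arr.reshape(-1, arr.shape[-1]).T  # (t, voxels)
    elif arr.ndim == 2:
        shape = (arr.shape[1],)
        Y = arr
    else:
        raise ValueError("bold must be 4-D (x,y,z,t) or 2-D (t,voxels)")
    return Y, shape


def first_level(bold, X) -> FirstLevelResult:
    """Per-voxel OLS of the time series on the design matrix.

    ``X`` may be the DataFrame from :func:`arcpipe.design.build_design_matrix`
    (or its ``DesignInfo`` wrapper) or a plain (t, p) array.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    import pandas as pd

    if hasattr(X, "matrix"):
        X = X.matrix
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        columns = [f"col_{i}" for i in range(Xm.shape[1])]
    Y, shape = _as_timeseries(bold)
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError(
            f"time dimension mismatch: bold has {Y.shape[0]} scans, design {Xm.shape[0]}"
        )
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify offending columns via the R diagonal of a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(Xm, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = [columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    beta, _, _, _ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    dof = Y.shape[0] - rank
    resid_var = (resid**2).sum(axis=0) / max(dof, 1)
    return FirstLevelResult(
        betas=beta.reshape(Xm.shape[1], *shape),
        resid_var=resid_var.reshape(shape),
        dof=dof,
        columns=columns,
        baseline_mean=Y.mean(axis=0).reshape(shape),
        shape=shape,
    )


def psc_convert(beta_map, task_column, baseline_mean_map) -> np.ndarray:
    """Percent signal change: 100 * beta * peak(unit-amplitude regressor) / baseline.

    The peak of the HRF-convolved unit-amplitude task column fixes the
    scaling convention (the HRF itself is unit-peak).  Voxels with
    non-positive baseline are masked to NaN.
    """
    beta = np.asarray(beta_map, dtype=float)
    base = np.asarray(baseline_mean_map, dtype=float)
    peak = float(np.max(np.abs(np.asarray(task_column, dtype=float))))
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * beta * peak / base
    psc = np.where(base > 0, psc, np.nan)
    return psc


# --------------------------------------------------------------------------
# second level
# --------------------------------------------------------------------------

def _flatten_maps(maps) -> tuple[np.ndarray, tuple]:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim == 2:
        return arr, (arr.shape[1],)
    return arr.reshape(arr.shape[0], -1), arr.shape[1:]


def _wls_intercept_F(Y, Z, weights):
    """F statistic for the intercept of Y ~ 1 + Z, per voxel (vectorized).

    Returns (F, dof_resid).  Zero-residual voxels yield +inf with a warning
    suppressed to keep permutation loops quiet.
    """
    n = Y.shape[0]
    X = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    p = X.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Yw = Y * sw[:, None]
    XtXinv = np.linalg.inv(Xw.T @ Xw)
    H = XtXinv @ Xw.T
    b = H @ Yw
    resid = Yw - Xw @ b
    dof = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (resid**2).sum(axis=0) / dof
        F = b[0] ** 2 / (s2 * XtXinv[0, 0])
    return F, dof


def second_level_wls(subject_maps, covariates=None, weights=None):
    """Weighted least-squares group model with an intercept F-contrast.

    ``subject_maps`` is (n_subjects, ...) PSC maps; ``covariates`` (n, q)
    nuisance regressors (e.g. a scanner indicator); ``weights`` positive WLS
    weights (default: unit weights, i.e. OLS as the WLS special case).
    Returns the F map testing the group mean against zero.
    """
    Y, shape = _flatten_maps(subject_maps)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    Z = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z is not None and Z.shape[0] != Y.shape[0]:
        Z = Z.T
    if Z is not None and np.linalg.matrix_rank(np.column_stack([np.ones(Y.shape[0]), Z])) < 1 + Z.shape[1]:
        raise ValueError("covariates are rank deficient with the intercept")
    F, _ = _wls_intercept_F(Y, Z, weights)
    if np.any(~np.isfinite(F)):
        warnings.warn("zero-residual voxels produced non-finite F; check degenerate input")
    return F.reshape(shape)


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (
                    (connectivity == 6 and order == 1)
                    or (connectivity == 18 and order <= 2)
                    or connectivity == 26
                ):
                    offs.append((dx, dy, dz))
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    return np.asarray(offs, dtype=np.int64)


@njit(cache=True)
def _tfce_kernel(stat, step, H, E, offs):
    # per threshold, only voxels at or above it are touched: voxels are
    # pre-sorted by height and each level visits the sorted prefix, with a
    # per-level stamp array replacing a visited reset
    nx, ny, nz = stat.shape
    nv = nx * ny * nz
    out = np.zeros_like(stat)
    flat = stat.ravel()
    m = flat.max()
    if m <= 0.0:
        return out
    n_steps = int(m / step + 1e-9)
    order = np.argsort(-flat, kind="mergesort")
    sorted_vals = flat[order]
    out_flat = out.ravel()
    stamp = np.zeros(nv, dtype=np.int64)
    queue = np.empty(nv, dtype=np.int64)
    sy = nz
    sx = ny * nz
    vx = np.empty(nv, dtype=np.int32)
    vy = np.empty(nv, dtype=np.int32)
    vz = np.empty(nv, dtype=np.int32)
    for v in range(nv):
        vx[v] = v // sx
        vy[v] = (v % sx) // sy
        vz[v] = v % sy
    for s in range(1, n_steps + 1):
        h = s * step
        thr = h - 1e-12
        # number of suprathreshold voxels = prefix length in sorted order
        lo, hi_i = 0, nv
        while lo < hi_i:
            mid = (lo + hi_i) // 2
            if sorted_vals[mid] >= thr:
                lo = mid + 1
            else:
                hi_i = mid
        n_above = lo
        for i in range(n_above):
            v = order[i]
            if stamp[v] == s:
                continue
            head = 0
            tail = 0
            queue[tail] = v
            tail += 1
            stamp[v] = s
            while head < tail:
                c = queue[head]
                head += 1
                cx = vx[c]
                cy = vy[c]
                cz = vz[c]
                for o in range(offs.shape[0]):
                    ax = cx + offs[o, 0]
                    ay = cy + offs[o, 1]
                    az = cz + offs[o, 2]
                    if 0 <= ax < nx and 0 <= ay < ny and 0 <= az < nz:
                        a = ax * sx + ay * sy + az
                        if stamp[a] != s and flat[a] >= thr:
                            stamp[a] = s
                            queue[tail] = a
                            tail += 1
            val = step * h**H * tail**E
            for t in range(tail):
                out_flat[queue[t]] += val
    return out


def tfce(
    stat_map,
    H: float = TFCE_H,
    E: float = TFCE_E,
    step: float = TFCE_STEP,
    connectivity: int = 6,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    For each voxel, sums extent(h)^E * h^H * step over thresholds
    h = step, 2*step, ... up to the voxel's height, where extent(h) is the
    size of the suprathreshold connected component containing the voxel.
    Negative values are enhanced separately on the sign-flipped map and
    subtracted, so both tails are represented.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    stat = np.ascontiguousarray(stat_map, dtype=float)
    if stat.ndim != 3:
        raise ValueError("stat_map must be 3-D")
    if not np.all(np.isfinite(stat)):
        raise ValueError("stat_map must be finite")
    offs = _neighbor_offsets(connectivity)
    pos = _tfce_kernel(np.maximum(stat, 0.0), step, H, E, offs)
    if np.any(stat < 0):
        neg = _tfce_kernel(np.maximum(-stat, 0.0), step, H, E, offs)
        return pos - neg
    return pos


# --------------------------------------------------------------------------
# Freedman-Lane permutation inference
# --------------------------------------------------------------------------

@dataclass
class GroupResult:
    f_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p: np.ndarray
    max_distribution: np.ndarray
    labels: np.ndarray
    alpha: float


def freedman_lane_permute(
    subject_maps,
    covariates=None,
    n_perms: int = 5000,
    seed: int = 0,
    weights=None,
    permute: str = "sign",
    H: float = TFCE_H,
    E: float = TFCE_E,
    step: float = TFCE_STEP,
    connectivity: int = 6,
):
    """Permutation max-TFCE null distribution for the group-mean contrast.

    Following Freedman-Lane, the nuisance-only model (covariates without the
    tested intercept) is fitted, its residuals are resampled — sign-flipped
    by default, or row-permuted with ``permute="rows"`` — the nuisance fit
    is added back, and the full model's F and TFCE maps are recomputed.
    Returns (max_distribution, observed_tfce, observed_F).
    """
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    Y, shape = _flatten_maps(subject_maps)
    n = Y.shape[0]
    if len(shape) != 3:
        raise ValueError("subject maps must be 3-D volumes")
    if permute not in ("sign", "rows"):
        raise ValueError("permute must be 'sign' or 'rows'")
    n_distinct = 2**n if permute == "sign" else math.factorial(min(n, 20))
    if n_perms > n_distinct:
        warnings.warn(
            f"{n_perms} permutations exceed the {n_distinct} distinguishable ones; capped"
        )
        n_perms = n_distinct

    Z = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z is not None and Z.shape[0] != n:
        Z = Z.T

    # nuisance-only fit (an empty nuisance model has zero fitted values)
    if Z is None:
        fitted = np.zeros_like(Y)
        resid = Y
    else:
        bz, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ bz
        resid = Y - fitted

    def observed_stat():
        F, _ = _wls_intercept_F(Y, Z, weights)
        return F

    obs_F = observed_stat().reshape(shape)
    obs_tfce = tfce(obs_F, H=H, E=E, step=step, connectivity=connectivity)

    rng = np.random.default_rng(seed)
    max_dist = np.empty(n_perms)
    if permute == "sign" and Z is None and weights is None:
        # closed-form one-sample F for every sign pattern in one batch
        S = rng.choice([-1.0, 1.0], size=(n_perms, n))
        means = (S @ Y) / n
        ss = (Y**2).sum(axis=0)
        var = (ss - n * means**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_all = n * means**2 / var
        for p in range(n_perms):
            tp = tfce(F_all[p].reshape(shape), H=H, E=E, step=step,
                      connectivity=connectivity)
            max_dist[p] = tp.max()
        return max_dist, obs_tfce, obs_F
    for p in range(n_perms):
        if permute == "sign":
            signs = rng.choice([-1.0, 1.0], size=n)
            Ystar = fitted + signs[:, None] * resid
        else:
            perm = rng.permutation(n)
            Ystar = fitted + resid[perm]
        Fp, _ = _wls_intercept_F(Ystar, Z, weights)
        tp = tfce(Fp.reshape(shape), H=H, E=E, step=step, connectivity=connectivity)
        max_dist[p] = tp.max()
    return max_dist, obs_tfce, obs_F


def fwe_correct(observed_tfce, max_distribution) -> np.ndarray:
    """Voxelwise FWE-corrected p values from the permutation max distribution.

    p(v) = (1 + #{perm maxima >= observed(v)}) / (1 + n_perms); the add-one
    convention avoids zero p values and makes the test permutation-inclusive.
    """
    dist = np.asarray(max_distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("empty permutation distribution")
    obs = np.asarray(observed_tfce, dtype=float)
    counts = (dist[None, :] >= obs.reshape(-1, 1)).sum(axis=1)
    p = (1.0 + counts) / (1.0 + dist.size)
    return p.reshape(obs.shape)


def cluster_filter(
    thresholded_map,
    min_voxels: int = MIN_CLUSTER_VOXELS,
    connectivity: int = 6,
) -> np.ndarray:
    """Label suprathreshold clusters, discarding those below ``min_voxels``.

    Accepts a boolean mask or a map thresholded so that nonzero means
    suprathreshold.  The 20-voxel default mirrors the volumetric
    cluster-extent criterion.  Returns an integer label map (0 background).
    """
    mask = np.asarray(thresholded_map) != 0 if np.asarray(thresholded_map).dtype != bool \
        else np.asarray(thresholded_map)
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(mask.ndim, order)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_voxels)
    keep = keep[keep != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def group_inference(
    subject_maps,
    covariates=None,
    n_perms: int = 5000,
    alpha: float = ALPHA_FWE,
    seed: int = 0,
    weights=None,
    min_voxels: int = MIN_CLUSTER_VOXELS,
    connectivity: int = 6,
    **tfce_params,
) -> GroupResult:
    """Full second-level pipeline: WLS F, TFCE, permutation FWE, clusters."""
    max_dist, obs_tfce, obs_F = freedman_lane_permute(
        subject_maps, covariates=covariates, n_perms=n_perms, seed=seed,
        weights=weights, connectivity=connectivity, **tfce_params,
    )
    p = fwe_correct(obs_tfce, max_dist)
    labels = cluster_filter(p <= alpha, min_voxels=min_voxels, connectivity=connectivity)
    return GroupResult(
        f_map=obs_F,
        tfce_map=obs_tfce,
        fwe_p=p,
        max_distribution=max_dist,
        labels=labels,
        alpha=alpha,
    )
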