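"""Image-space quantification.

IDIF extraction by the sphere/threshold rule, regional TAC extraction
through a label atlas, voxel-wise Logan parametric maps, Gaussian smoothing
with missing-value masking, and voxel-wise two-group comparison with
permutation cluster inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid
from scipy.stats import t as t_dist

from .core import (
    ConfigurationError,
    DynamicImage,
    FWHM_PER_SIGMA,
    LabelAtlas,
    TimeActivityCurve,
    fine_time_grid,
)
from .kinetics import QualityError, _input_on_fine_grid, select_tstar

__all__ = [
    "ExtractionError",
    "extract_idif",
    "extract_regional_tacs",
    "parametric_logan_map",
    "gaussian_smooth",
    "voxelwise_group_compare",
]


class ExtractionError(RuntimeError):
    """IDIF extraction failed (no usable blood-pool signal)."""


# ---------------------------------------------------------------------------
# IDIF
# ---------------------------------------------------------------------------

def extract_idif(
    image: DynamicImage,
    heart_center_hint: tuple[float, float, float],
    sphere_diameter_mm: float = 3.5,
    threshold_frac: float = 0.5,
    early_window_min: float = 2.0,
    min_peak_kbq: float = 1.0,
) -> TimeActivityCurve:
    """Image-derived input function from the left-ventricle blood pool.

    A sphere (default 3.5 mm diameter) is centred on ``heart_center_hint``
    (mm). Among frames with midpoints inside the early window the frame of
    maximal in-sphere mean activity is found, voxels at or above
    ``threshold_frac`` of that frame's in-sphere maximum are retained (the
    set is fixed across frames), and their mean per frame is the IDIF. A
    ``threshold_frac`` of 1 or more keeps the single hottest voxel (first in
    scan order on ties). A peak below ``min_peak_kbq`` means the sphere
    missed the blood pool and raises :class:`ExtractionError`.
    """
    vs = image.voxel_size_mm
    center = np.asarray(heart_center_hint, dtype=float) / vs
    radius_vox = 0.5 * sphere_diameter_mm / vs
    shape = image.data.shape[:3]
    if np.any(center - radius_vox < -0.5) or np.any(center + radius_vox > np.array(shape) - 0.5):
        raise ConfigurationError("IDIF sphere does not fit inside the field of view")
    grid = np.indices(shape, dtype=float)
    dist2 = sum((grid[d] - center[d]) ** 2 for d in range(3))
    sphere = dist2 <= radius_vox**2
    if not sphere.any():
        raise ExtractionError("empty IDIF sphere")

    mids = image.schedule.mid_minutes
    early = np.flatnonzero(mids <= early_window_min)
    if early.size == 0:
        early = np.array([0])
    in_sphere = image.data[sphere, :]  # (nvox, nframes)
    peak_frame = int(early[np.argmax(in_sphere[:, early].mean(axis=0))])
    peak_vals = in_sphere[:, peak_frame]
    peak_max = float(peak_vals.max())
    if peak_max < min_peak_kbq:
        raise ExtractionError(
            f"in-sphere peak activity {peak_max:.2f} kBq/cm^3 below {min_peak_kbq}; "
            "sphere is off the blood pool"
        )
    if threshold_frac >= 1.0:
        keep = np.zeros(peak_vals.size, dtype=bool)
        keep[int(np.argmax(peak_vals))] = True
    else:
        keep = peak_vals >= threshold_frac * peak_max
    if not keep.any():
        raise ExtractionError("no voxels above the IDIF threshold")
    return TimeActivityCurve(image.schedule, in_sphere[keep, :].mean(axis=0), "IDIF")


# ---------------------------------------------------------------------------
# Regional TACs
# ---------------------------------------------------------------------------

def extract_regional_tacs(image: DynamicImage, atlas: LabelAtlas,
                          regions: list[str] | None = None) -> dict[str, TimeActivityCurve]:
    """Unweighted mean TAC over each atlas region."""
    if atlas.labels.shape != image.data.shape[:3]:
        raise ConfigurationError("atlas grid does not match the image grid")
    out = {}
    for region in (regions if regions is not None else atlas.regions):
        mask = atlas.mask(region)
        out[region] = TimeActivityCurve(
            image.schedule, image.data[mask, :].mean(axis=0, dtype=np.float64), str(region)
        )
    return out


# ---------------------------------------------------------------------------
# Voxel-wise Logan map
# ---------------------------------------------------------------------------

def parametric_logan_map(
    image: DynamicImage,
    idif,
    max_err: float = 0.10,
    t_star: float | None = None,
    per_voxel_tstar: bool = False,
    mask: np.ndarray | None = None,
    min_mean_kbq: float = 0.2,
) -> np.ndarray:
    """Voxel-wise Logan V_T map (NaN where unquantifiable).

    By default a single global t* is selected from the mean TAC over the
    quantified voxels and shared across the map; ``per_voxel_tstar`` applies
    the maximum-error criterion voxel by voxel instead. Voxels outside the
    mask (default: voxels whose time-averaged activity exceeds
    ``min_mean_kbq``), with non-positive late-frame activity, or failing the
    t* criterion are set to NaN, never 0.
    """
    schedule = image.schedule
    mids = schedule.mid_minutes
    dur = schedule.duration_minutes
    t = fine_time_grid(schedule)
    cp = _input_on_fine_grid(idif, t, schedule)
    int_cp = np.interp(mids, t, cumulative_trapezoid(cp, t, initial=0.0))

    data = image.data.reshape(-1, schedule.n_frames).astype(np.float64)
    w = dur / dur.sum()
    mean_act = data @ w
    vox_mask = mean_act > min_mean_kbq if mask is None else np.asarray(mask).reshape(-1)

    vt = np.full(data.shape[0], np.nan)
    idx = np.flatnonzero(vox_mask)
    if idx.size == 0:
        return vt.reshape(image.data.shape[:3])
    ct = data[idx, :]
    int_ct = np.cumsum(ct * dur[None, :], axis=1) - 0.5 * ct * dur[None, :]

    if t_star is None and not per_voxel_tstar:
        mean_tac = TimeActivityCurve(schedule, ct.mean(axis=0))
        from .kinetics import _logan_arrays
        x, y, times = _logan_arrays(mean_tac, idif)
        t_star = select_tstar(x, y, times, max_err=max_err)

    if per_voxel_tstar:
        from .kinetics import logan_vt
        for row, i in enumerate(idx):
            tac = TimeActivityCurve(schedule, ct[row])
            try:
                vt[i] = logan_vt(tac, idif, max_err=max_err).vt
            except (QualityError, ConfigurationError):
                pass
        return vt.reshape(image.data.shape[:3])

    use = mids >= t_star - 1e-9
    ct_u = ct[:, use]
    ok = np.all(ct_u > 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = int_cp[None, use] / ct_u
        y = int_ct[:, use] / ct_u
    n = use.sum()
    sx = x.sum(axis=1)
    sy = y.sum(axis=1)
    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    denom = sxx - sx * sx / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sxy - sx * sy / n) / denom
    slope[~ok | ~np.isfinite(slope)] = np.nan
    vt[idx] = slope
    return vt.reshape(image.data.shape[:3])


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def gaussian_smooth(map3d: np.ndarray, fwhm_mm: float = 0.5,
                    voxel_size_mm: float = 0.776) -> np.ndarray:
    """Isotropic Gaussian smoothing with normalized masking of NaNs.

    sigma = FWHM / 2.3548, converted to voxels. NaN voxels are excluded by
    smoothing the zero-filled map and the finite-mask weight separately and
    taking their ratio; originally-NaN voxels stay NaN.
    """
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return map3d.copy()
    sigma = fwhm_mm / FWHM_PER_SIGMA / voxel_size_mm
    finite = np.isfinite(map3d)
    filled = np.where(finite, map3d, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="constant")
    den = ndimage.gaussian_filter(finite.astype(float), sigma, mode="constant")
    out = np.full_like(filled, np.nan)
    good = den > 1e-12
    out[good] = num[good] / den[good]
    out[~finite] = np.nan
    return out


# ---------------------------------------------------------------------------
# Voxel-wise group comparison with permutation cluster inference
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _tmap(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t-map (A minus B) over axis 0."""
    a = data[is_a]
    b = data[~is_a]
    na, nb = a.shape[0], b.shape[0]
    ma = a.mean(axis=0)
    mb = b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lab, n = ndimage.label(supra, structure=_CONN26)
    if n == 0:
        return lab, np.array([], dtype=int)
    return lab, np.bincount(lab.ravel())[1:]


def voxelwise_group_compare(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    peak_p: float = 0.05,
    min_extent_voxels: int = 100,
    cluster_p: float = 0.05,
    n_permutations: int = 500,
    voxel_size_mm: float = 0.776,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-group voxel-wise comparison with cluster-extent inference.

    A pooled two-sample t-map is thresholded at the one-sided uncorrected
    ``peak_p`` in both directions (A>B and B>A); 26-connected clusters of at
    least ``min_extent_voxels`` receive a cluster-level p-value from a
    group-label permutation null of the maximum supra-threshold cluster
    extent (maximum over both contrasts, so the reported p-values are
    familywise over direction). Returns the table of clusters significant at
    ``cluster_p`` and the t-map (NaN outside the common finite mask).
    """
    data = np.stack(list(maps_a) + list(maps_b)).astype(np.float64)
    na, nb = len(maps_a), len(maps_b)
    if min(na, nb) < 2:
        raise ConfigurationError("need at least 2 maps per group")
    if n_permutations + 1 < 1.0 / cluster_p:
        warnings.warn(
            f"{n_permutations} permutations cannot resolve p < {cluster_p}", stacklevel=2
        )
    finite = np.all(np.isfinite(data), axis=0)
    data[:, ~finite] = 0.0
    df = na + nb - 2
    t_crit = float(t_dist.isf(peak_p, df))
    is_a = np.zeros(na + nb, dtype=bool)
    is_a[:na] = True

    tmap = _tmap(data, is_a)
    tmap[~finite] = 0.0

    # observed candidate clusters, both contrasts
    candidates = []
    for direction, sign in (("A>B", 1.0), ("B>A", -1.0)):
        lab, sizes = _cluster_sizes((sign * tmap >= t_crit) & finite)
        for ci, size in enumerate(sizes, start=1):
            if size >= min_extent_voxels:
                in_c = lab == ci
                peak_idx = np.unravel_index(
                    np.argmax(np.where(in_c, sign * tmap, -np.inf)), tmap.shape
                )
                candidates.append({
                    "direction": direction,
                    "n_voxels": int(size),
                    "volume_mm3": float(size * voxel_size_mm**3),
                    "peak_t": float(sign * tmap[peak_idx]) if sign > 0 else float(tmap[peak_idx]),
                    "peak_ijk": tuple(int(v) for v in peak_idx),
                    "cluster_mask": in_c,
                })

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(na + nb)
        t_p = _tmap(data[perm], is_a)
        t_p[~finite] = 0.0
        m = 0
        for sign in (1.0, -1.0):
            _, sizes = _cluster_sizes((sign * t_p >= t_crit) & finite)
            if sizes.size:
                big = sizes.max()
                m = max(m, int(big) if big >= min_extent_voxels else 0)
        null_max[p] = m

    rows = []
    for c in candidates:
        pval = (1.0 + np.sum(null_max >= c["n_voxels"])) / (n_permutations + 1.0)
        if pval < cluster_p:
            c = dict(c, p_value=float(pval))
            rows.append(c)
    table = pd.DataFrame(
        rows,
        columns=["direction", "n_voxels", "volume_mm3", "peak_t", "peak_ijk",
                 "p_value", "cluster_mask"],
    )
    out_t = np.where(finite, tmap, np.nan)
    return table, out_t
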