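"""Kinetic quantification: 2TCM fitting, Logan graphical analysis with
automatic t*, DVR-1, and reference-tissue models (SRTM / SRTM2).

All fits are deterministic given the data and configuration: the 2TCM uses a
fixed multi-start set and the reference models a fixed basis grid. Weighted
least squares uses frame-duration weights (w proportional to frame length)
throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares, minimize_scalar

from .core import (
    ConfigurationError,
    InputFunctionParams,
    KineticParams,
    TimeActivityCurve,
    _exp_conv,
    fine_time_grid,
    frame_average,
    input_function,
    tissue_curve_2tcm,
)

__all__ = [
    "Fit2TCMResult",
    "LoganResult",
    "SRTMResult",
    "SRTM2Result",
    "fit_2tcm",
    "logan_vt",
    "select_tstar",
    "dvr_minus_one",
    "fit_srtm",
    "fit_srtm2",
    "estimate_k2prime_group",
    "DEFAULT_K2A_GRID",
]


class QualityError(RuntimeError):
    """Data fail a model's applicability criterion."""


def _input_on_fine_grid(input_, t, schedule=None):
    """Plasma input sampled on the fine minute grid ``t``.

    Accepts either analytic bolus parameters or a framed (IDIF-like) TAC,
    which is interpolated linearly through its frame midpoints with a zero
    anchor at t = 0 and a flat hold past the last midpoint.
    """
    if isinstance(input_, InputFunctionParams):
        return input_function(input_, t)
    if isinstance(input_, TimeActivityCurve):
        mids = input_.schedule.mid_minutes
        return np.interp(t, np.concatenate([[0.0], mids]),
                         np.concatenate([[0.0], input_.activity]))
    raise TypeError("input must be InputFunctionParams or TimeActivityCurve")


def _frame_weights(schedule) -> np.ndarray:
    w = schedule.duration_minutes
    return w / w.sum()


# ---------------------------------------------------------------------------
# 2TCM nonlinear fit
# ---------------------------------------------------------------------------

@dataclass
class Fit2TCMResult:
    K1: float
    k2: float
    k3: float
    k4: float
    V_B: float
    ssr: float
    converged: bool

    @property
    def vt(self) -> float:
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


#: fixed multi-start grid spanning the documented rate ranges
_STARTS_2TCM = [
    (k1, k2, k3, 0.1)
    for k1, k2, k3 in itertools.product((0.3, 0.6), (0.1, 0.4), (0.1, 0.5))
]
_BOUNDS_2TCM = (np.array([1e-4] * 4), np.array([5.0, 5.0, 5.0, 2.0]))


def fit_2tcm(tac: TimeActivityCurve, input_, v_b: float = 0.036) -> Fit2TCMResult:
    """Weighted nonlinear 2TCM fit with the blood volume fraction fixed.

    ``input_`` may be analytic bolus parameters or a framed input TAC; the
    same curve serves as the whole-blood term (no plasma/whole-blood or
    metabolite correction). Eight fixed starting points are tried and the
    best-residual solution returned; ties break toward the smallest
    parameter norm. Non-convergence of every start is flagged on the result
    rather than raised.
    """
    schedule = tac.schedule
    t = fine_time_grid(schedule)
    cp = _input_on_fine_grid(input_, t, schedule)
    w = np.sqrt(_frame_weights(schedule))
    y = tac.activity

    def model_frames(p):
        k1, k2, k3, k4 = p
        s = k2 + k3 + k4
        disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
        th1, th2 = 0.5 * (s + disc), 0.5 * (s - disc)
        if th1 - th2 < 1e-6 * th1:
            eps = 5e-7 * th1
            th1, th2 = th1 + eps, th2 - eps
        a = k3 + k4
        ct = k1 / (th1 - th2) * (
            (th1 - a) * _exp_conv(th1, t, cp) + (a - th2) * _exp_conv(th2, t, cp)
        )
        curve = (1.0 - v_b) * ct + v_b * cp
        return frame_average(curve, t, schedule).activity

    def residuals(p):
        return w * (model_frames(p) - y)

    best = None
    any_converged = False
    for start in _STARTS_2TCM:
        try:
            res = least_squares(residuals, np.array(start), bounds=_BOUNDS_2TCM,
                                x_scale=np.array([0.5, 0.3, 0.3, 0.1]), ftol=1e-10,
                                xtol=1e-10, gtol=1e-10, max_nfev=400)
        except Exception:
            continue
        ssr = float(2.0 * res.cost)
        key = (ssr, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
        any_converged = any_converged or bool(res.success)
    if best is None:
        return Fit2TCMResult(np.nan, np.nan, np.nan, np.nan, v_b, np.inf, False)
    (ssr, _), res = best
    k1, k2, k3, k4 = res.x
    return Fit2TCMResult(float(k1), float(k2), float(k3), float(k4), v_b, ssr,
                         any_converged)


# ---------------------------------------------------------------------------
# Logan graphical analysis
# ---------------------------------------------------------------------------

@dataclass
class LoganResult:
    vt: float
    intercept: float
    t_star: float
    n_points_used: int
    max_rel_error: float


def _logan_arrays(tac: TimeActivityCurve, input_):
    """Logan regressor/response at frame midpoints.

    y = int_0^t C_T / C_T(t) against x = int_0^t C_p / C_T(t); the tissue
    running integral uses the frame-step representation (exact at
    midpoints), the input integral a trapezoid on the fine grid.
    """
    schedule = tac.schedule
    mids = schedule.mid_minutes
    ct = tac.activity
    dur = schedule.duration_minutes
    int_ct = np.cumsum(ct * dur) - 0.5 * ct * dur
    t = fine_time_grid(schedule)
    cp = _input_on_fine_grid(input_, t, schedule)
    int_cp_fine = cumulative_trapezoid(cp, t, initial=0.0)
    int_cp = np.interp(mids, t, int_cp_fine)
    ok = ct > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(ok, int_cp / ct, np.nan)
        y = np.where(ok, int_ct / ct, np.nan)
    return x[ok], y[ok], mids[ok]


def select_tstar(x: np.ndarray, y: np.ndarray, times: np.ndarray,
                 max_err: float = 0.10, min_points: int = 3) -> float:
    """Earliest time from which the Logan plot is linear.

    Returns the smallest frame midpoint t such that an ordinary
    least-squares line through all points from t onward has maximum absolute
    relative residual (|y - yhat| / |yhat|) at most ``max_err``.
    """
    x, y, times = map(np.asarray, (x, y, times))
    n = x.size
    for i in range(0, n - min_points + 1):
        slope, icpt = np.polyfit(x[i:], y[i:], 1)
        yhat = slope * x[i:] + icpt
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(y[i:] - yhat) / np.abs(yhat)
        if np.nanmax(rel) <= max_err:
            return float(times[i])
    raise QualityError(f"no linear phase satisfies the {max_err:.0%} maximum-error criterion")


def logan_vt(tac: TimeActivityCurve, input_, max_err: float = 0.10,
             t_star: float | None = None) -> LoganResult:
    """Logan distribution volume: slope of the late linear phase.

    When ``t_star`` is not given it is selected by the maximum-error
    criterion (default 10%) over frame-midpoint candidates.
    """
    x, y, times = _logan_arrays(tac, input_)
    if t_star is None:
        t_star = select_tstar(x, y, times, max_err=max_err)
    use = times >= t_star - 1e-9
    if use.sum() < 3:
        raise QualityError("fewer than 3 frames beyond t*")
    slope, icpt = np.polyfit(x[use], y[use], 1)
    yhat = slope * x[use] + icpt
    with np.errstate(divide="ignore", invalid="ignore"):
        max_rel = float(np.nanmax(np.abs(y[use] - yhat) / np.abs(yhat)))
    return LoganResult(float(slope), float(icpt), float(t_star), int(use.sum()), max_rel)


def dvr_minus_one(vt_target: float, vt_reference: float) -> float:
    """Distribution volume ratio minus one: target V_T over reference V_T, minus 1."""
    if vt_reference <= 0:
        raise ConfigurationError("reference V_T must be positive")
    return vt_target / vt_reference - 1.0


# ---------------------------------------------------------------------------
# Reference tissue models
# ---------------------------------------------------------------------------

DEFAULT_K2A_GRID = np.geomspace(0.006, 0.6, 64)


@dataclass
class SRTMResult:
    R1: float
    k2: float
    k2a: float
    bp_nd: float
    on_boundary: bool

    @property
    def k2_prime(self) -> float:
        return self.k2 / self.R1

    @property
    def failed(self) -> bool:
        # failure criterion: boundary optimum or non-physical parameters
        return self.on_boundary or min(self.R1, self.k2, self.bp_nd + 1.0) <= 0


@dataclass
class SRTM2Result:
    R1: float
    k2a: float
    bp_nd: float
    k2_prime_used: float
    on_boundary: bool


def _ref_basis(ref_tac: TimeActivityCurve):
    schedule = ref_tac.schedule
    t = fine_time_grid(schedule)
    cr_fine = _input_on_fine_grid(ref_tac, t, schedule)
    cr_frames = frame_average(cr_fine, t, schedule).activity
    def basis(k2a):
        return frame_average(_exp_conv(k2a, t, cr_fine), t, schedule).activity
    return cr_frames, basis


def fit_srtm(tac: TimeActivityCurve, ref_tac: TimeActivityCurve,
             k2a_grid: np.ndarray = DEFAULT_K2A_GRID) -> SRTMResult:
    """Three-parameter simplified reference tissue model via basis functions.

    For each k2a on the grid, C_T is regressed on C_R and C_R (x)
    exp(-k2a t) (weighted linear LS); the best-residual k2a wins. Used for
    first-pass k2' estimation; a boundary-of-grid optimum or non-physical
    parameters mark the fit as failed.
    """
    w = _frame_weights(tac.schedule)
    y = tac.activity
    cr, basis = _ref_basis(ref_tac)
    best = None
    for i, k2a in enumerate(k2a_grid):
        b = basis(k2a)
        a11 = np.sum(w * cr * cr)
        a12 = np.sum(w * cr * b)
        a22 = np.sum(w * b * b)
        r1 = np.sum(w * cr * y)
        r2 = np.sum(w * b * y)
        det = a11 * a22 - a12 * a12
        if det <= 0:
            continue
        th1 = (a22 * r1 - a12 * r2) / det
        th2 = (a11 * r2 - a12 * r1) / det
        ssr = float(np.sum(w * (y - th1 * cr - th2 * b) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, i, th1, th2)
    if best is None:
        raise QualityError("SRTM basis fit degenerate for all k2a")
    _, i, th1, th2 = best
    k2a = float(k2a_grid[i])
    k2 = th2 + th1 * k2a
    return SRTMResult(float(th1), float(k2), k2a, float(k2 / k2a - 1.0),
                      i in (0, len(k2a_grid) - 1))


def fit_srtm2(tac: TimeActivityCurve, ref_tac: TimeActivityCurve,
              k2_prime: float, k2a_grid: np.ndarray = DEFAULT_K2A_GRID,
              refine: bool = True) -> SRTM2Result:
    """Two-parameter SRTM with the reference efflux rate k2' fixed.

    With k2' fixed the model is linear in R1 alone for each candidate k2a:
    C_T = R1 * [C_R + (k2' - k2a) * (C_R (x) exp(-k2a t))]. The basis grid is
    scanned, optionally followed by a deterministic bounded refinement
    between the best point's neighbours. BP_ND = R1 * k2' / k2a - 1.
    """
    if k2_prime <= 0:
        raise ConfigurationError("k2_prime must be positive")
    w = _frame_weights(tac.schedule)
    y = tac.activity
    cr, basis = _ref_basis(ref_tac)

    def sse_r1(k2a):
        m = cr + (k2_prime - k2a) * basis(k2a)
        denom = np.sum(w * m * m)
        r1 = np.sum(w * m * y) / denom if denom > 0 else 0.0
        return float(np.sum(w * (y - r1 * m) ** 2)), float(r1)

    scores = [sse_r1(k)[0] for k in k2a_grid]
    i = int(np.argmin(scores))
    k2a = float(k2a_grid[i])
    on_boundary = i in (0, len(k2a_grid) - 1)
    if refine and not on_boundary:
        lo, hi = k2a_grid[i - 1], k2a_grid[i + 1]
        res = minimize_scalar(lambda k: sse_r1(k)[0], bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-5})
        k2a = float(res.x)
    _, r1 = sse_r1(k2a)
    bp = r1 * k2_prime / k2a - 1.0
    return SRTM2Result(r1, k2a, float(bp), float(k2_prime), on_boundary)


def estimate_k2prime_group(first_pass, grouping=None) -> dict:
    """Group-averaged reference efflux rate for second-pass SRTM2.

    ``first_pass`` is a table (pandas DataFrame) of per-subject, per-region
    first-pass k2' estimates with a ``k2_prime`` column; ``grouping`` names
    the column defining the groups (default ``genotype``). Returns the
    arithmetic mean k2' per group, averaged across regions and subjects.
    """
    import pandas as pd

    table = pd.DataFrame(first_pass)
    if "k2_prime" not in table.columns:
        raise ConfigurationError("first_pass must carry a k2_prime column")
    grouping = grouping or "genotype"
    if table.empty:
        raise ConfigurationError("no first-pass fits supplied")
    if grouping not in table.columns:
        return {"all": float(table.k2_prime.mean())}
    out = table.groupby(grouping).k2_prime.mean().to_dict()
    if any(np.isnan(v) for v in out.values()):
        raise ConfigurationError("a group has no valid first-pass k2' estimates")
    return {k: float(v) for k, v in out.items()}
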