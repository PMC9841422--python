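"""Per-molecule trajectory model fitting.

The workhorse of the pipeline: every molecule's intensity-versus-time series
is fitted with a continuous three-segment piecewise-linear function

    f(x) = m*a + t   for x < a
           m*x + t   for a <= x <= b
           m*b + t   for x > b

where ``a`` marks the onset of enzymatic activity, ``b`` its completion and
``m`` the constant processive slope.  The fitted plateaus define a
per-molecule intensity calibration (1 = full template, 0 = none) so that
|m| on the calibrated scale, times the template length in base pairs, is the
enzymatic rate in nt/s.  Sudden single-frame intensity drops (strand
dissociation, tether rupture) are located with an exhaustive single-split
two-level model, i.e. a depth-1 regression tree on time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import CalibrationError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Length of the standard linear dsDNA template in base pairs.
TEMPLATE_BP = 2620

_MIN_POINTS = 8


@dataclass
class PiecewiseFit:
    """Parameters of the three-segment piecewise-linear fit."""

    m: float          # slope during activity (input-intensity units per s)
    t: float          # intercept of the central segment
    a: float          # activity start (s)
    b: float          # activity end (s)
    r2: float         # coefficient of determination of the full fit
    n_points: int
    sse: float = np.nan
    degenerate: bool = False

    @property
    def plateau_pre(self) -> float:
        return self.m * self.a + self.t

    @property
    def plateau_post(self) -> float:
        return self.m * self.b + self.t

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.m * np.clip(np.asarray(x, float), self.a, self.b) + self.t


@dataclass
class CalibratedTrajectory:
    """Trajectory on the per-molecule calibrated intensity scale.

    1 maps to the full template (pre-reaction plateau of a decreasing
    signal), 0 to none.  ``bp`` is the calibrated value scaled by the
    template length.  Individual points may leave [0, 1] through noise.
    """

    times: np.ndarray
    i_cal: np.ndarray
    direction: str                      # "decreasing" | "increasing"
    template_bp: int = TEMPLATE_BP
    molecule_id: int | None = None

    @property
    def bp(self) -> np.ndarray:
        return self.i_cal * self.template_bp


@dataclass
class ChangePoint:
    """Best two-level (single split) step model of a trajectory."""

    t_drop: float       # first time of the lower segment (s)
    pre_level: float
    post_level: float
    score: float        # fraction of variance explained by the step model


@dataclass
class RateDistribution:
    """Per-molecule enzymatic rates and summary statistics."""

    rates: np.ndarray
    template_bp: int

    @property
    def n(self) -> int:
        return self.rates.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates)) if self.n else np.nan

    @property
    def std(self) -> float:
        return float(np.std(self.rates, ddof=1)) if self.n > 1 else np.nan

    @property
    def median(self) -> float:
        return float(np.median(self.rates)) if self.n else np.nan


def robust_noise_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute first difference.

    For additive white noise of scale sigma, successive differences have
    scale sigma*sqrt(2); the MAD-based estimate is insensitive to the slow
    piecewise-linear signal underneath.
    """
    d = np.diff(np.asarray(values, float))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def _grid_sse(times, values, cand):
    """SSE of the piecewise-linear OLS fit for every candidate (a, b) pair.

    For fixed (a, b) the model is linear in (m, t) with regressor
    z = clip(x, a, b); prefix sums make every cell O(1).  Returns
    (sse_matrix, m_matrix, t_matrix) over cand x cand with rows = a index,
    cols = b index (cells with b < a set to +inf).
    """
    x = times
    y = values
    n = x.size
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cx2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    sy = cy[-1]
    syy_c = float(np.sum((y - sy / n) ** 2))

    ia = cand[:, None]
    ib = cand[None, :]
    a = x[cand][:, None]
    b = x[cand][None, :]
    n_left = ia.astype(float)
    n_right = (n - 1 - ib).astype(float)

    sz = a * n_left + (cx[ib + 1] - cx[ia]) + b * n_right
    sz2 = a * a * n_left + (cx2[ib + 1] - cx2[ia]) + b * b * n_right
    szy = a * cy[ia] + (cxy[ib + 1] - cxy[ia]) + b * (sy - cy[ib + 1])

    szz_c = sz2 - sz * sz / n
    szy_c = szy - sz * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(szz_c > 1e-12, szy_c / np.where(szz_c > 1e-12, szz_c, 1.0), 0.0)
    sse = syy_c - m * szy_c
    sse = np.where(ib >= ia, sse, np.inf)
    t = (sy - m * sz) / n
    return sse, m, t


def _best_grid_cell(times, values, cand):
    sse, m, t = _grid_sse(times, values, cand)
    # C-order argmin: ties resolve toward the smaller a, then the smaller b
    flat = int(np.argmin(sse))
    i, j = np.unravel_index(flat, sse.shape)
    return cand[i], cand[j], float(m[i, j]), float(t[i, j]), float(sse[i, j])


def _subsample(lo: int, hi: int, max_points: int) -> np.ndarray:
    """Integer index grid over [lo, hi] with at most max_points entries."""
    span = hi - lo
    if span + 1 <= max_points:
        return np.arange(lo, hi + 1)
    return np.unique(np.linspace(lo, hi, max_points).round().astype(int))


def _model_residuals(theta, x, y):
    m, t, a, d = theta
    return m * np.clip(x, a, a + d) + t - y


def _model_jac(theta, x, y):
    m, t, a, d = theta
    b = a + d
    z = np.clip(x, a, b)
    jac = np.empty((x.size, 4))
    jac[:, 0] = z
    jac[:, 1] = 1.0
    left = x < a
    right = x > b
    jac[:, 2] = m * (left | right)
    jac[:, 3] = m * right
    return jac


def fit_piecewise_linear(
    times: np.ndarray,
    values: np.ndarray,
    max_grid: int = 120,
    refine: bool = True,
) -> PiecewiseFit:
    """Least-squares fit of the three-segment piecewise-linear model.

    Strategy: an (a, b) grid on frame boundaries with closed-form (m, t)
    per cell (exhaustive when the trajectory has <= ``max_grid`` frames,
    subsampled plus a local fine pass otherwise), then bounded nonlinear
    refinement of all four parameters with an analytic Jacobian.  ``a <= b``
    is enforced by optimising (a, b - a >= 0).

    Raises
    ------
    InsufficientDataError
        for fewer than 8 points.
    """
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    if x.size != y.size:
        raise ValueError("times and values must have equal length")
    if x.size < _MIN_POINTS:
        raise InsufficientDataError(
            f"piecewise fit needs >= {_MIN_POINTS} points, got {x.size}"
        )
    n = x.size
    sst = float(np.sum((y - y.mean()) ** 2))

    if sst <= 0.0:
        # zero-variance input: (a, b) unidentifiable
        return PiecewiseFit(
            m=0.0, t=float(y[0]), a=np.nan, b=np.nan, r2=np.nan,
            n_points=n, sse=0.0, degenerate=True,
        )

    cand = _subsample(0, n - 1, max_grid)
    ia, ib, m0, t0, sse0 = _best_grid_cell(x, y, cand)
    if cand.size < n:
        # frame-resolution pass around each coarse change point
        step = int(np.max(np.diff(cand)))
        neigh = []
        for i0 in (ia, ib):
            lo = max(0, i0 - 2 * step)
            hi = min(n - 1, i0 + 2 * step)
            neigh.append(_subsample(lo, hi, max_grid))
        cand2 = np.unique(np.concatenate(neigh))
        ia2, ib2, m2, t2, sse2 = _best_grid_cell(x, y, cand2)
        if sse2 <= sse0:
            ia, ib, m0, t0, sse0 = ia2, ib2, m2, t2, sse2

    a0, b0 = float(x[ia]), float(x[ib])
    best = (m0, t0, a0, b0, sse0)

    if refine:
        span = float(x[-1] - x[0])
        theta0 = np.array([m0, t0, a0, b0 - a0])
        try:
            res = least_squares(
                _model_residuals, theta0, jac=_model_jac, args=(x, y),
                bounds=([-np.inf, -np.inf, x[0] - span, 0.0],
                        [np.inf, np.inf, x[-1] + span, 2.0 * span]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                x_scale=[1.0, 1.0, max(span / 10.0, 1e-6), max(span / 10.0, 1e-6)],
            )
            sse_ref = float(2.0 * res.cost)
            if res.success and sse_ref <= best[4]:
                m1, t1, a1, d1 = res.x
                best = (float(m1), float(t1), float(a1), float(a1 + d1), sse_ref)
        except Exception:  # refinement is best-effort; the grid fit stands
            logger.debug("piecewise refinement failed; keeping grid fit")

    m, t, a, b, sse = best
    r2 = 1.0 - sse / sst
    fit = PiecewiseFit(m=m, t=t, a=a, b=b, r2=r2, n_points=n, sse=sse)
    plateau_diff = abs(m) * (b - a)
    if plateau_diff < 3.0 * robust_noise_sigma(y):
        fit.degenerate = True
    return fit


def calibrate(
    times: np.ndarray,
    values: np.ndarray,
    fit: PiecewiseFit,
    direction: str = "decreasing",
    template_bp: int = TEMPLATE_BP,
    molecule_id: int | None = None,
) -> CalibratedTrajectory:
    """Map raw intensity to the calibrated [0, 1] scale.

    For a decreasing signal  I_cal = (I - (m*b + t)) / ((m*a + t) - (m*b + t));
    for an increasing signal (e.g. the ssDNA/RPA channel) the roles of a and
    b swap, so the post-activity plateau maps to 1.
    """
    if direction not in ("decreasing", "increasing"):
        raise ValueError(f"unknown direction {direction!r}")
    if fit.degenerate or not np.isfinite(fit.a):
        raise CalibrationError("cannot calibrate a degenerate fit")
    pre, post = fit.plateau_pre, fit.plateau_post
    if direction == "increasing":
        pre, post = post, pre
    denom = pre - post
    if denom == 0.0:
        raise CalibrationError("plateau levels are equal; calibration refused")
    i_cal = (np.asarray(values, float) - post) / denom
    return CalibratedTrajectory(
        times=np.asarray(times, float), i_cal=i_cal,
        direction=direction, template_bp=template_bp, molecule_id=molecule_id,
    )


def detect_drop(
    times: np.ndarray,
    values: np.ndarray,
    min_score: float = 0.5,
) -> ChangePoint | None:
    """Locate a sudden intensity drop with a depth-1 regression tree.

    Exhaustive search over all single split points for the two-level
    piecewise-constant model minimising the within-segment sum of squares.
    Returns the change point only if the later level is lower and the
    fraction of variance explained reaches ``min_score``; otherwise None.
    """
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    n = y.size
    if n < _MIN_POINTS:
        raise InsufficientDataError(
            f"drop detection needs >= {_MIN_POINTS} points, got {n}"
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        return None

    cy = np.concatenate(([0.0], np.cumsum(y)))
    cy2 = np.concatenate(([0.0], np.cumsum(y * y)))
    k = np.arange(1, n)                       # split before index k
    sse_left = cy2[k] - cy[k] ** 2 / k
    nr = n - k
    sse_right = (cy2[-1] - cy2[k]) - (cy[-1] - cy[k]) ** 2 / nr
    sse = sse_left + sse_right
    kbest = int(k[np.argmin(sse)])
    pre = float(cy[kbest] / kbest)
    post = float((cy[-1] - cy[kbest]) / (n - kbest))
    score = 1.0 - float(sse[kbest - 1]) / sst
    if post >= pre or score < min_score:
        return None
    return ChangePoint(t_drop=float(x[kbest]), pre_level=pre,
                       post_level=post, score=score)


def filter_trajectories(
    fits: list[PiecewiseFit],
    n_frames,
    frame_interval: float,
    r2_min: float = 0.7,
    require_drop: bool = False,
    drops: list[ChangePoint | None] | None = None,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Quality-filter fitted molecules; every discard carries a reason.

    Incomplete reactions — negative ``a`` or ``b``, or ``a``/``b`` beyond
    the end of the movie — are discarded, as are fits whose coefficient of
    determination does not exceed ``r2_min``.  In strand-displacement mode
    (``require_drop``) molecules without a confirming dissociation drop are
    discarded as well.  ``n_frames`` may be a scalar or per-molecule array.

    Returns (kept indices, [(index, reason), ...]).
    """
    n_frames = np.broadcast_to(np.asarray(n_frames), (len(fits),))
    if require_drop and drops is None:
        raise ValueError("require_drop=True needs the drops list")
    kept: list[int] = []
    discarded: list[tuple[int, str]] = []
    for i, f in enumerate(fits):
        t_end = float(n_frames[i]) * frame_interval
        if f.degenerate:
            discarded.append((i, "degenerate: no resolvable activity"))
        elif f.a < 0:
            discarded.append((i, "incomplete: a < 0"))
        elif f.b < 0:
            discarded.append((i, "incomplete: b < 0"))
        elif f.a > t_end:
            discarded.append((i, "incomplete: a > movie end"))
        elif f.b > t_end:
            discarded.append((i, "incomplete: b > movie end"))
        elif not (f.r2 > r2_min):
            discarded.append((i, f"r2 <= {r2_min}"))
        elif require_drop and drops[i] is None:
            discarded.append((i, "no confirming intensity drop"))
        else:
            kept.append(i)
    return kept, discarded


def compute_rates(
    fits: list[PiecewiseFit],
    template_bp: int = TEMPLATE_BP,
) -> RateDistribution:
    """Per-molecule rates |m| * template_bp from calibrated-scale fits.

    On the calibrated scale |m| is the processed fraction of the template
    per second, so the product is the enzymatic rate in nt/s.
    """
    rates = np.array([abs(f.m) * template_bp for f in fits], float)
    return RateDistribution(rates=rates, template_bp=template_bp)
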