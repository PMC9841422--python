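"""Ensemble- and event-level kinetic inference.

Covers the exponential strand-displacement synthesis fit, Michaelis-Menten
dependence on dNTP concentration, pseudo-first-order RPA binding, survival
curves of tethered substrates and shifted-gamma first-passage-time (FPT)
analysis.

The gamma FPT model treats the waiting time to an irreversible terminal
event (tether rupture) as the sum of n identical exponential steps: with a
fixed offset x0 for reagent arrival, the density on x > x0 is

    f(x; n, k) = k^n (x - x0)^(n-1) exp(-k (x - x0)) / Gamma(n)

and the fitted shape n estimates the number of rate-limiting reaction
intermediates (n = 1 reduces to an exponential, i.e. no intermediates).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import FitError, InsufficientDataError, ParameterError
from .imageproc import Trajectory
from .trajfit import TEMPLATE_BP, detect_drop

logger = logging.getLogger(__name__)

DEFAULT_X0_S = 20.0          # s, ATP arrival offset for FPT fitting
DEFAULT_RPA_CONC_NM = 20.0   # nM labelled RPA in solution


@dataclass
class ExpFit:
    """Single-exponential synthesis fit exp(k (x - x0)) to the RPA signal."""

    k: float                  # 1/s
    x0: float                 # s
    template_bp: int = TEMPLATE_BP
    fit_window_max: float = -10.0
    n_points: int = 0

    @property
    def rate_bp_s(self) -> float:
        return self.k * self.template_bp


@dataclass
class MMFit:
    """Michaelis-Menten fit v = v_max [S] / (K_M + [S])."""

    K_M: float                # uM
    v_max: float              # bp/s
    K_M_stderr: float = np.nan
    v_max_stderr: float = np.nan

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, float)
        return self.v_max * c / (self.K_M + c)


@dataclass
class RPABindingFit:
    """Pseudo-first-order RPA binding fit on the nt-scaled ensemble.

    Model: [ssDNA_RPA](x) = template_nt - ssDNA_free_0 * exp(-k_exp (x - x0))
    with x0 held fixed (only ssDNA_free_0 * exp(k_exp * x0) is identifiable,
    so the offset is an input, not a fitted parameter).  The reported
    bimolecular association constant uses the declared convention
    k_on = k_exp * template_nt / [RPA], recorded in every manifest.
    """

    k_exp: float              # 1/s
    ssDNA_free_0: float       # nt
    x0: float                 # s (fixed)
    template_nt: int = TEMPLATE_BP
    rpa_conc: float = DEFAULT_RPA_CONC_NM     # nM
    convention: str = "k_on = k_exp * template_nt / rpa_conc_nM"

    @property
    def k_on_reported(self) -> float:
        return self.k_exp * self.template_nt / self.rpa_conc


@dataclass
class FPTSet:
    """Per-molecule first-passage times with censoring flags."""

    event_times: np.ndarray
    censored: np.ndarray
    t_reagent_arrival: float = DEFAULT_X0_S

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, float)
        self.censored = np.asarray(self.censored, bool)
        if self.event_times.shape != self.censored.shape:
            raise ParameterError("event_times and censored must align")
        if np.any(self.event_times < 0):
            raise ParameterError("event times must be >= 0")

    @property
    def n_total(self) -> int:
        return self.event_times.size

    @property
    def events(self) -> np.ndarray:
        """Uncensored event times."""
        return self.event_times[~self.censored]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


@dataclass
class GammaFit:
    """Shifted-gamma MLE of an FPT distribution (x0 fixed)."""

    n: float                  # shape: number of reaction intermediates
    k: float                  # 1/s
    x0: float
    log_likelihood: float
    n_events: int
    n_dropped: int = 0        # events at or before x0, excluded

    @property
    def mean_fpt(self) -> float:
        return self.x0 + self.n / self.k


@dataclass
class SurvivalCurve:
    """Fraction of substrates still tethered over time (not Kaplan-Meier:
    censored molecules never leave the denominator)."""

    times: np.ndarray
    fraction_bound: np.ndarray
    n_total: int

    def at(self, t) -> np.ndarray:
        """Fraction bound evaluated at arbitrary times (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        return self.fraction_bound[np.clip(idx, 0, self.times.size - 1)]


# ---------------------------------------------------------------------------
# ensemble fits

def fit_exponential_synthesis(
    rel_times: np.ndarray,
    rpa_mean: np.ndarray,
    template_bp: int = TEMPLATE_BP,
    window_max: float = -10.0,
) -> ExpFit:
    """Fit exp(k (x - x0)) to the synchronised, normalised RPA signal.

    Only rel_times strictly below ``window_max`` enter the fit: close to
    the synchronisation point the RPA signal saturates and is no longer
    single-exponential.  The synthesis rate in bp/s is k * template_bp.
    """
    x = np.asarray(rel_times, float)
    y = np.asarray(rpa_mean, float)
    sel = x < window_max
    if sel.sum() < 10:
        raise InsufficientDataError(
            f"need >= 10 ensemble points before {window_max} s, have {int(sel.sum())}")
    x, y = x[sel], y[sel]

    pos = y > 0
    if pos.sum() >= 2:
        slope, icpt = np.polyfit(x[pos], np.log(y[pos]), 1)
        k0 = max(slope, 1e-4)
        x00 = -icpt / k0
    else:
        k0, x00 = 0.05, 0.0
    try:
        with warnings.catch_warnings():
            # (k, x0) covariance is singular for noiseless input; only the
            # point estimates are used here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, k, x0: np.exp(np.clip(k * (x - x0), -700.0, 700.0)),
                x, y, p0=(k0, x00), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential synthesis fit failed: {exc}") from exc
    k, x0 = popt
    if k <= 0:
        raise FitError(f"non-positive synthesis rate constant k = {k:.4g}")
    return ExpFit(k=float(k), x0=float(x0), template_bp=template_bp,
                  fit_window_max=window_max, n_points=int(x.size))


def fit_michaelis_menten(
    concs: np.ndarray,
    rates: np.ndarray,
    sems: np.ndarray | None = None,
) -> MMFit:
    """Weighted nonlinear least-squares fit of the Michaelis-Menten equation."""
    c = np.asarray(concs, float)
    v = np.asarray(rates, float)
    if np.unique(c).size < 3:
        raise InsufficientDataError("need >= 3 distinct substrate concentrations")
    sigma = None if sems is None else np.asarray(sems, float)
    p0 = (np.median(c), float(v.max()) * 1.2 + 1e-9)
    try:
        popt, pcov = optimize.curve_fit(
            lambda c, km, vmax: vmax * c / (km + c), c, v,
            p0=p0, sigma=sigma, absolute_sigma=sigma is not None, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
    km, vmax = popt
    if km <= 0 or vmax <= 0:
        raise FitError("Michaelis-Menten fit returned non-positive parameters")
    perr = np.sqrt(np.diag(pcov))
    return MMFit(K_M=float(km), v_max=float(vmax),
                 K_M_stderr=float(perr[0]), v_max_stderr=float(perr[1]))


def fit_rpa_binding(
    rel_times: np.ndarray,
    rpa_nt: np.ndarray,
    x0: float = 0.0,
    rpa_conc: float = DEFAULT_RPA_CONC_NM,
    template_nt: int = TEMPLATE_BP,
    window_min: float = -20.0,
) -> RPABindingFit:
    """First-order RPA binding fit on the nt-scaled synchronised signal.

    Fits template_nt - f0 * exp(-k (x - x0)) for rel_time >= window_min
    (earlier points are dominated by synthesis, not binding).  ``x0`` is a
    fixed time offset, not optimised (see RPABindingFit).
    """
    x = np.asarray(rel_times, float)
    y = np.asarray(rpa_nt, float)
    sel = x >= window_min
    if sel.sum() < 5:
        raise InsufficientDataError("too few ensemble points in the binding window")
    x, y = x[sel], y[sel]

    resid = template_nt - y
    pos = resid > 0
    if pos.sum() < 3 or np.ptp(y) < 1e-9:
        raise FitError("saturated or flat input: no curvature to fit")
    slope, icpt = np.polyfit(x[pos] - x0, np.log(resid[pos]), 1)
    k0 = max(-slope, 1e-4)
    f00 = math.exp(icpt)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, k, f0: template_nt - f0 * np.exp(-k * (x - x0)), x, y,
            p0=(k0, f00), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"RPA binding fit failed: {exc}") from exc
    k_exp, f0 = popt
    if k_exp <= 0 or not (0 < f0 <= template_nt * 1.5):
        raise FitError("RPA binding fit returned parameters outside their domain")
    return RPABindingFit(k_exp=float(k_exp), ssDNA_free_0=float(f0), x0=x0,
                         template_nt=template_nt, rpa_conc=rpa_conc)


# ---------------------------------------------------------------------------
# first-passage times

def extract_fpts(
    trajs: list[Trajectory],
    movie_end: float,
    min_score: float = 0.5,
    channel: str | None = None,
    t_reagent_arrival: float = DEFAULT_X0_S,
) -> FPTSet:
    """First-passage times from single-step disappearance trajectories.

    Per molecule the FPT is the drop time found by the exhaustive
    single-split step detector; molecules without a qualifying drop are
    censored at ``movie_end`` (still tethered when the movie stopped).
    """
    events, censored = [], []
    for tr in trajs:
        y = tr.channels[channel] if channel else tr.primary
        cp = detect_drop(tr.times, y, min_score=min_score)
        if cp is None:
            events.append(movie_end)
            censored.append(True)
        else:
            events.append(cp.t_drop)
            censored.append(False)
    return FPTSet(event_times=np.array(events), censored=np.array(censored),
                  t_reagent_arrival=t_reagent_arrival)


def survival_curve(fpts: FPTSet) -> SurvivalCurve:
    """Fraction of substrates still bound: (n_total - events <= t) / n_total.

    Censored molecules never decrement the curve.
    """
    n = fpts.n_total
    ev = np.sort(fpts.events)
    times = np.concatenate(([0.0], ev))
    frac = np.concatenate(([1.0], 1.0 - np.arange(1, ev.size + 1) / n)) if n else \
        np.array([1.0])
    # collapse tied event times to the last (lowest) level
    keep = np.concatenate((np.diff(times) > 0, [True]))
    return SurvivalCurve(times=times[keep], fraction_bound=frac[keep], n_total=n)


def _gamma_mle_shape(s: float) -> float:
    """Solve log(n) - digamma(n) = s (profile likelihood shape equation)."""
    if s <= 0:
        raise FitError("degenerate FPT sample: zero log-spread")
    # Minka's initialisation, then bracketed root refinement
    n0 = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    f = lambda n: math.log(n) - special.digamma(n) - s
    lo, hi = n0 / 10.0, n0 * 10.0
    while f(lo) < 0:
        lo /= 10.0
        if lo < 1e-12:
            raise FitError("gamma MLE shape equation has no root in range")
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise FitError("gamma MLE shape equation has no root in range")
    return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def gamma_method_of_moments(y: np.ndarray) -> tuple[float, float]:
    """(shape, rate) from the first two moments of offset-free waiting times."""
    mean = float(np.mean(y))
    var = float(np.var(y, ddof=1))
    if var <= 0:
        raise FitError("zero-variance waiting times")
    return mean * mean / var, mean / var


def fit_gamma_fpt(
    fpts: FPTSet,
    x0: float = DEFAULT_X0_S,
    min_events: int = 50,
) -> GammaFit:
    """Maximum-likelihood shifted-gamma fit with the offset x0 held fixed.

    Uncensored events at or before x0 (reagent still arriving) are dropped
    with a logged count.  The shape MLE solves log(n) - digamma(n) =
    log(mean) - mean(log); the rate then follows as n / mean.  On the rare
    non-convergence a FitError carries the method-of-moments estimate.
    """
    ev = fpts.events
    y = ev[ev > x0] - x0
    n_dropped = int(ev.size - y.size)
    if n_dropped:
        logger.info("dropped %d event(s) at or before x0 = %g s", n_dropped, x0)
    if y.size < min_events:
        raise InsufficientDataError(
            f"gamma MLE needs >= {min_events} events after x0, have {y.size}")
    s = math.log(float(np.mean(y))) - float(np.mean(np.log(y)))
    try:
        shape = _gamma_mle_shape(s)
    except FitError as exc:
        mom = gamma_method_of_moments(y)
        raise FitError(
            f"gamma MLE failed ({exc}); method-of-moments estimate "
            f"shape={mom[0]:.4g}, rate={mom[1]:.4g}") from exc
    rate = shape / float(np.mean(y))
    ll = float(np.sum(stats.gamma.logpdf(y, a=shape, scale=1.0 / rate)))
    return GammaFit(n=shape, k=rate, x0=x0, log_likelihood=ll,
                    n_events=int(y.size), n_dropped=n_dropped)


def exponential_loglik(fpts: FPTSet, x0: float = DEFAULT_X0_S) -> tuple[float, float]:
    """MLE rate and log-likelihood of the nested exponential (n = 1) model."""
    ev = fpts.events
    y = ev[ev > x0] - x0
    if y.size == 0:
        raise InsufficientDataError("no events after x0")
    k = 1.0 / float(np.mean(y))
    ll = float(y.size * math.log(k) - k * np.sum(y))
    return k, ll
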