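"""Displacement, velocity and acceleration profiles from calibrated tracks.

The chain is: chord-summed cumulative arc length of the tracked point ->
angular displacement theta = s / L -> penalized quintic smoothing spline of
theta(t) -> analytic first and second derivatives of the fitted spline for
angular velocity omega and acceleration alpha -> linear kinematics v = omega*L,
a = alpha*L (SI units). Peaks are extracted on a dense evaluation grid
(>= 10x the input sampling) so that low frame rates do not bias peak values
to sample instants; ties in peak location resolve to the earliest time.

The smoother is a P-spline: a degree-5 B-spline basis on equally spaced
knots with a difference penalty on the coefficients, the penalty weight
chosen by generalized cross-validation (GCV) unless the caller fixes it or
requests a target effective degrees of freedom. Derivatives are the exact
derivatives of the fitted B-spline, never finite differences of samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from trapjaw.io import CalibratedTrajectory

SPLINE_DEGREE = 5

#: default difference-penalty order; its null space (quadratics in t) leaves
#: constant-acceleration motion completely unpenalized
DEFAULT_PENALTY_ORDER = 3

#: GCV search grid for the penalty weight (time is normalized to [0, 1]
#: internally, so the grid is scale-free in t)
_LAMBDA_GRID = np.logspace(-14.0, 6.0, 61)


@dataclass
class DisplacementSeries:
    """Cumulative arc-length displacement of the tracked point, with theta = s/L."""

    times: np.ndarray          # s
    s_mm: np.ndarray           # cumulative chord-summed arc length, mm
    theta_rad: np.ndarray      # s_mm / L
    cheliceral_length_mm: float
    specimen_id: str = ""
    strike_id: str = ""
    side: str = ""


@dataclass
class SplineFit:
    """Penalized quintic smoothing spline of theta(t) and its derivatives."""

    degree: int
    lambda_: float             # penalty weight on the normalized time axis
    edf: float                 # effective degrees of freedom, trace of the hat matrix
    residual_sd: float         # rad
    t_start: float
    t_end: float
    cheliceral_length_mm: float
    _spline: BSpline = field(repr=False)
    _span: float = field(repr=False)
    specimen_id: str = ""
    strike_id: str = ""
    side: str = ""

    def _u(self, t):
        return (np.asarray(t, dtype=float) - self.t_start) / self._span

    def theta(self, t) -> np.ndarray:
        """Fitted angular displacement, rad."""
        self._check_domain(t)
        return self._spline(self._u(t))

    def omega(self, t) -> np.ndarray:
        """Analytic first derivative, rad/s."""
        self._check_domain(t)
        return self._spline.derivative(1)(self._u(t)) / self._span

    def alpha(self, t) -> np.ndarray:
        """Analytic second derivative, rad/s^2."""
        self._check_domain(t)
        return self._spline.derivative(2)(self._u(t)) / self._span**2

    def _check_domain(self, t) -> None:
        t = np.asarray(t, dtype=float)
        tol = 1e-12 * max(1.0, abs(self.t_end))
        if np.any(t < self.t_start - tol) or np.any(t > self.t_end + tol):
            raise ValueError(
                f"evaluation outside fitted interval [{self.t_start}, {self.t_end}]"
            )


@dataclass
class KinematicProfile:
    """Smoothed angular and linear kinematics of one chelicera (or a pair average)."""

    times: np.ndarray          # dense evaluation grid, s
    theta: np.ndarray          # rad
    omega: np.ndarray          # rad/s
    alpha: np.ndarray          # rad/s^2
    v: np.ndarray              # m/s
    a: np.ndarray              # m/s^2
    peak_omega: float
    peak_alpha: float
    peak_v: float
    peak_a: float
    t_peak_omega: float        # s, earliest maximizer
    sweep_rad: float           # theta(end) - theta(start)
    duration_s: float          # first-to-last digitized frame
    cheliceral_length_mm: float
    specimen_id: str = ""
    strike_id: str = ""
    side: str = ""
    smoothing_lambda: float = float("nan")
    smoothing_edf: float = float("nan")
    averaged_from_single_chelicera: bool = False


def cumulative_arc_length(traj: CalibratedTrajectory) -> DisplacementSeries:
    """Chord-sum approximation s[i] = sum_j ||p_j - p_{j-1}||, theta = s / L.

    Step lengths are unsigned, so noise-induced back-steps accumulate —
    this matches the "cumulative displacement" convention of tracked-point
    digitization rather than a signed angle.
    """
    if traj.cheliceral_length_mm <= 0:
        raise ValueError("cheliceral length must be positive")
    pts = np.asarray(traj.points_mm, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for arc length")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return DisplacementSeries(
        times=np.asarray(traj.times, dtype=float),
        s_mm=s,
        theta_rad=s / traj.cheliceral_length_mm,
        cheliceral_length_mm=traj.cheliceral_length_mm,
        specimen_id=traj.specimen_id,
        strike_id=traj.strike_id,
        side=traj.side,
    )


def _basis(u: np.ndarray, nseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Open-uniform degree-5 B-spline basis on [0, 1] with nseg segments."""
    interior = np.linspace(0.0, 1.0, nseg + 1)
    knots = np.concatenate([np.zeros(SPLINE_DEGREE), interior, np.ones(SPLINE_DEGREE)])
    B = BSpline.design_matrix(u, knots, SPLINE_DEGREE, extrapolate=False).toarray()
    return B, knots


def _solve_penalized(BtB, Bty, P, lam):
    return np.linalg.solve(BtB + lam * P, Bty)


def _edf(BtB, P, lam) -> float:
    return float(np.trace(np.linalg.solve(BtB + lam * P, BtB)))


def fit_quintic_spline(
    series: DisplacementSeries,
    smoothing: float | None = None,
    df: float | None = None,
    nseg: int | None = None,
    penalty_order: int = DEFAULT_PENALTY_ORDER,
) -> SplineFit:
    """Fit a penalized degree-5 smoothing spline to theta(t).

    Parameters
    ----------
    smoothing
        Penalty weight lambda (on the time axis normalized to [0, 1]).
        When omitted, lambda is selected by minimizing the GCV score
        ``n * RSS / (n - edf)^2`` over a wide logarithmic grid.
    df
        Alternatively, a target effective degrees of freedom; lambda is
        solved so the hat-matrix trace matches it. Mutually exclusive with
        ``smoothing``.
    nseg
        Number of equal B-spline segments; defaults to a size that keeps
        the basis smaller than the sample count.
    penalty_order
        Order of the difference penalty on the B-spline coefficients.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.theta_rad, dtype=float)
    n = len(t)
    if n < SPLINE_DEGREE + 1:
        raise ValueError(f"need at least {SPLINE_DEGREE + 1} samples, got {n}")
    if len(np.unique(t)) != n or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and distinct")
    if smoothing is not None and df is not None:
        raise ValueError("give either smoothing or df, not both")
    if smoothing is not None and smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    span = t[-1] - t[0]
    u = (t - t[0]) / span
    if nseg is None:
        # keep the basis near half the sample count: large enough for any
        # plausible closure profile, small enough that GCV cannot drive the
        # fit to interpolation of digitization noise
        nseg = max(1, min(35, -(-n // 2) - SPLINE_DEGREE))
    K = nseg + SPLINE_DEGREE
    if penalty_order >= K:
        raise ValueError("penalty_order must be smaller than the basis size")
    B, knots = _basis(u, nseg)
    D = np.diff(np.eye(K), n=penalty_order, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    # tiny ridge keeps the normal equations solvable when K ~ n and lam -> 0
    BtB_reg = BtB + 1e-12 * np.eye(K)
    Bty = B.T @ y

    if smoothing is not None:
        lam = float(smoothing)
    elif df is not None:
        lam = _lambda_for_df(BtB_reg, P, float(df))
    else:
        lam = _gcv_lambda(B, y, BtB_reg, Bty, P)

    coef = _solve_penalized(BtB_reg, Bty, P, lam)
    fitted = B @ coef
    resid = y - fitted
    edf = _edf(BtB_reg, P, lam)
    dof_resid = max(n - edf, 1.0)
    return SplineFit(
        degree=SPLINE_DEGREE,
        lambda_=lam,
        edf=edf,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof_resid)),
        t_start=float(t[0]),
        t_end=float(t[-1]),
        cheliceral_length_mm=series.cheliceral_length_mm,
        _spline=BSpline(knots, coef, SPLINE_DEGREE),
        _span=float(span),
        specimen_id=series.specimen_id,
        strike_id=series.strike_id,
        side=series.side,
    )


def _gcv_lambda(B, y, BtB, Bty, P) -> float:
    n = len(y)
    best_lam, best_score = _LAMBDA_GRID[0], np.inf
    for lam in _LAMBDA_GRID:
        coef = _solve_penalized(BtB, Bty, P, lam)
        rss = float(np.sum((y - B @ coef) ** 2))
        edf = _edf(BtB, P, lam)
        denom = n - edf
        if denom <= 0.5:
            continue
        score = n * rss / denom**2
        if score < best_score:
            best_score, best_lam = score, lam
    return float(best_lam)


def _lambda_for_df(BtB, P, target_df: float) -> float:
    """Bisection on log-lambda for trace(H(lambda)) = target_df (monotone)."""
    lo, hi = _LAMBDA_GRID[0], _LAMBDA_GRID[-1]
    if not _edf(BtB, P, hi) <= target_df <= _edf(BtB, P, lo):
        raise ValueError(
            f"target df {target_df} outside attainable range "
            f"[{_edf(BtB, P, hi):.2f}, {_edf(BtB, P, lo):.2f}]"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _edf(BtB, P, mid) > target_df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def differentiate(
    fit: SplineFit,
    times: np.ndarray | None = None,
    dense_factor: int = 10,
    n_input: int | None = None,
) -> KinematicProfile:
    """Evaluate omega, alpha (and v = omega*L, a = alpha*L) and extract peaks.

    Evaluation uses a dense uniform grid with at least ``dense_factor`` times
    the input sampling so that peaks falling between video frames are not
    missed. ``np.argmax`` resolves ties to the earliest grid time.
    """
    if times is None:
        n_pts = max(200, dense_factor * (n_input or 200))
        times = np.linspace(fit.t_start, fit.t_end, n_pts)
    times = np.asarray(times, dtype=float)
    theta = fit.theta(times)
    omega = fit.omega(times)
    alpha = fit.alpha(times)
    L_m = fit.cheliceral_length_mm * 1e-3
    v = omega * L_m
    a = alpha * L_m
    i_w = int(np.argmax(omega))
    i_a = int(np.argmax(np.abs(alpha)))
    return KinematicProfile(
        times=times,
        theta=theta,
        omega=omega,
        alpha=alpha,
        v=v,
        a=a,
        peak_omega=float(omega[i_w]),
        peak_alpha=float(np.abs(alpha[i_a])),
        peak_v=float(omega[i_w] * L_m),
        peak_a=float(np.abs(alpha[i_a]) * L_m),
        t_peak_omega=float(times[i_w]),
        sweep_rad=float(theta[-1] - theta[0]),
        duration_s=float(fit.t_end - fit.t_start),
        cheliceral_length_mm=fit.cheliceral_length_mm,
        specimen_id=fit.specimen_id,
        strike_id=fit.strike_id,
        side=fit.side,
        smoothing_lambda=fit.lambda_,
        smoothing_edf=fit.edf,
    )


def strike_window(
    series: DisplacementSeries,
    threshold_frac: float | None = None,
    fit: SplineFit | None = None,
) -> tuple[float, float, float]:
    """Strike window (t_start, t_end, duration).

    Default definition: from first to last digitized point, matching a
    digitization protocol that marks frames from the open to the closed
    position. With ``threshold_frac`` in (0, 1), the window is instead the
    span where the fitted angular velocity is >= threshold_frac * peak.
    """
    t = np.asarray(series.times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 digitized frames to define a duration")
    if threshold_frac is None:
        return float(t[0]), float(t[-1]), float(t[-1] - t[0])
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if fit is None:
        fit = fit_quintic_spline(series)
    grid = np.linspace(fit.t_start, fit.t_end, max(2000, 10 * len(t)))
    w = fit.omega(grid)
    mask = w >= threshold_frac * np.max(w)
    idx = np.nonzero(mask)[0]
    t0, t1 = float(grid[idx[0]]), float(grid[idx[-1]])
    return t0, t1, t1 - t0


def average_chelicerae(
    left: KinematicProfile | None,
    right: KinematicProfile | None,
) -> KinematicProfile:
    """Average the two synchronously striking chelicerae of one strike.

    Scalar summaries (peaks, duration, sweep) are arithmetic means of the two
    sides; series are averaged on the overlapping portion of their time grids.
    If one chelicera is missing the other passes through, flagged as such.
    """
    if left is None and right is None:
        raise ValueError("both chelicerae missing")
    if left is None or right is None:
        only = left if right is None else right
        out = dataclasses.replace(only, side="avg", averaged_from_single_chelicera=True)
        return out
    if (left.specimen_id, left.strike_id) != (right.specimen_id, right.strike_id):
        raise ValueError(
            f"mismatched strike identity: {left.specimen_id}/{left.strike_id} "
            f"vs {right.specimen_id}/{right.strike_id}"
        )
    t0 = max(left.times[0], right.times[0])
    t1 = min(left.times[-1], right.times[-1])
    if t1 <= t0:
        raise ValueError("no overlapping time support between chelicerae")
    grid = np.linspace(t0, t1, max(len(left.times), len(right.times)))

    def avg(attr):
        a = np.interp(grid, left.times, getattr(left, attr))
        b = np.interp(grid, right.times, getattr(right, attr))
        return 0.5 * (a + b)

    mean = lambda attr: 0.5 * (getattr(left, attr) + getattr(right, attr))
    return KinematicProfile(
        times=grid,
        theta=avg("theta"),
        omega=avg("omega"),
        alpha=avg("alpha"),
        v=avg("v"),
        a=avg("a"),
        peak_omega=mean("peak_omega"),
        peak_alpha=mean("peak_alpha"),
        peak_v=mean("peak_v"),
        peak_a=mean("peak_a"),
        t_peak_omega=mean("t_peak_omega"),
        sweep_rad=mean("sweep_rad"),
        duration_s=mean("duration_s"),
        cheliceral_length_mm=mean("cheliceral_length_mm"),
        specimen_id=left.specimen_id,
        strike_id=left.strike_id,
        side="avg",
        smoothing_lambda=float("nan"),
        smoothing_edf=mean("smoothing_edf"),
    )


def analyze_track(
    track,
    smoothing: float | None = None,
    df: float | None = None,
    dense_factor: int = 10,
) -> KinematicProfile:
    """Full single-chelicera chain: calibrate -> arc length -> spline -> profile."""
    from trapjaw.io import TrackedStrike, calibrate

    if isinstance(track, TrackedStrike):
        track = calibrate(track)
    series = cumulative_arc_length(track)
    fit = fit_quintic_spline(series, smoothing=smoothing, df=df)
    return differentiate(fit, dense_factor=dense_factor, n_input=len(series.times))
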