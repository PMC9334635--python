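"""Descriptive statistics of confined-molecule trajectories.

Covers the full observational chain: centroid tracking from fluorescence
movies, position histograms and free-energy maps, two-molecule separation
vector and alignment order parameter, pole-swap and pole-dwell statistics
with exponential fits, per-axis mean-squared displacement with short-time
power-law exponents, and radially/elliptically averaged density profiles
for crowding comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

from .errors import ConfigurationError, DataError, FitError, TrackingError
from .fields import ScalarField, make_grid
from .geometry import CavityGeometry, effective_radius
from .landscape_dynamics import Trajectory, landscape_from_probability

__all__ = [
    "SeparationSeries",
    "DwellTimeStats",
    "MSDResult",
    "RadialProfile",
    "subtract_background",
    "fluorescence_cm",
    "track_movie",
    "position_histogram",
    "free_energy_map",
    "separation_series",
    "order_parameter",
    "detect_swaps",
    "fit_exponential_dwell",
    "pole_dwell_times",
    "fit_double_exponential",
    "msd_per_axis",
    "fit_msd_exponent",
    "contour_profile",
    "distribution_edge",
    "edge_shift",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SeparationSeries:
    """Separation vector r = r1 - r2 of a two-molecule system over time."""

    times: np.ndarray  # s
    separation_vectors: np.ndarray  # (n, 2) um
    theta: np.ndarray  # angle to the minor (+y) axis, folded to [0, pi)
    normalized_projection: np.ndarray  # (r . x-hat) / semi_major
    semi_major: float


@dataclass
class DwellTimeStats:
    """Dwell-time samples in a two-state (or pole) assignment."""

    dwell_samples: np.ndarray  # s, uncensored events
    n_events: int
    censored_first: float | None = None  # s, duration of the censored edges
    censored_last: float | None = None
    tau: float | None = None
    tau_long: float | None = None
    tau_short: float | None = None
    weight_long: float | None = None
    fit_uncertainty: float | None = None
    extra: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dwell_samples = np.asarray(self.dwell_samples, dtype=float)
        if np.any(self.dwell_samples <= 0):
            raise DataError("dwell samples must be positive")
        self.n_events = len(self.dwell_samples)


@dataclass
class MSDResult:
    """Per-axis time-averaged MSD curves and fitted short-time exponents."""

    lags: np.ndarray  # s, excluding lag 0
    msd_parallel: np.ndarray  # um^2, major axis
    msd_perpendicular: np.ndarray  # um^2, minor axis
    alpha_parallel: float | None = None
    alpha_perpendicular: float | None = None
    alpha_parallel_stderr: float | None = None
    alpha_perpendicular_stderr: float | None = None
    fit_window: tuple[float, float] | None = None


@dataclass
class RadialProfile:
    """Binned density profile versus a normalized radial coordinate."""

    bin_centers: np.ndarray  # normalized in [0, 1]
    density: np.ndarray  # mean probability density per bin (um^-2); NaN = empty
    mode: str  # "radial" | "elliptical"
    physical_scale: float  # um per unit normalized coordinate
    flags: dict = _dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def subtract_background(image: np.ndarray, border_width: int = 3,
                        threshold_sigmas: float = 3.0) -> np.ndarray:
    """Median-of-border background subtraction with a noise floor, clamped at 0.

    The background level and its scatter are estimated over a border ring of
    ``border_width`` pixels (median and MAD-based sigma); pixels are reduced
    by median + ``threshold_sigmas`` * sigma and clamped at zero.  The noise
    floor matters: without it the clamped positive residuals of shot noise
    act as a uniform pedestal that biases intensity centroids toward the
    frame centre.  This is a deliberately simple, documented scheme suited
    to the synthetic movies produced here (uniform background plus shot
    noise).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise DataError("empty image")
    if border_width < 1 or 2 * border_width >= min(img.shape):
        raise ConfigurationError("border ring is empty for this image size")
    ring = np.concatenate([
        img[:border_width, :].ravel(),
        img[-border_width:, :].ravel(),
        img[border_width:-border_width, :border_width].ravel(),
        img[border_width:-border_width, -border_width:].ravel(),
    ])
    level = np.median(ring)
    sigma = 1.4826 * np.median(np.abs(ring - level))
    return np.clip(img - level - threshold_sigmas * sigma, 0.0, None)


def fluorescence_cm(image: np.ndarray, pixel_size: float,
                    origin: tuple[float, float]) -> np.ndarray:
    """Intensity-weighted centroid r_CM = sum(r I) / sum(I), cavity frame.

    ``origin`` is the cavity-frame coordinate of the centre of pixel
    [0, 0]; rows advance along +y.
    """
    img = np.asarray(image, dtype=float)
    total = img.sum()
    if total <= 0:
        raise TrackingError("zero total intensity; frame cannot be tracked")
    ny, nx = img.shape
    xs = origin[0] + pixel_size * np.arange(nx)
    ys = origin[1] + pixel_size * np.arange(ny)
    x_cm = (img.sum(axis=0) @ xs) / total
    y_cm = (img.sum(axis=1) @ ys) / total
    return np.array([x_cm, y_cm])


def track_movie(movies: dict[str, np.ndarray], pixel_size: float,
                frame_interval: float, origin: tuple[float, float],
                border_width: int = 3) -> dict[str, Trajectory]:
    """Centroid-track one or more aligned channel stacks.

    Parameters
    ----------
    movies : mapping channel label -> (n_frames, ny, nx) stack.

    Frames whose background-subtracted intensity vanishes in *any* channel
    are dropped consistently across channels so the channels stay
    frame-aligned.
    """
    labels = list(movies)
    n_frames = {k: len(v) for k, v in movies.items()}
    if len(set(n_frames.values())) != 1:
        raise DataError("channel stacks have different frame counts")
    nf = next(iter(n_frames.values()))
    if nf < 2:
        raise DataError("need at least 2 frames")

    positions = {k: [] for k in labels}
    kept = []
    for i in range(nf):
        frame_pos = {}
        ok = True
        for k in labels:
            img = subtract_background(movies[k][i], border_width)
            try:
                frame_pos[k] = fluorescence_cm(img, pixel_size, origin)
            except TrackingError:
                ok = False
                break
        if ok:
            kept.append(i)
            for k in labels:
                positions[k].append(frame_pos[k])
    if len(kept) < 2:
        raise TrackingError("fewer than 2 trackable frames in the movie")
    return {
        k: Trajectory(positions=np.array(positions[k]),
                      frame_interval=frame_interval, label=k)
        for k in labels
    }


# ---------------------------------------------------------------------------
# position statistics
# ---------------------------------------------------------------------------

def position_histogram(trajs: list[Trajectory] | Trajectory,
                       cavity: CavityGeometry, bin_size: float = 0.05,
                       template: ScalarField | None = None) -> ScalarField:
    """Normalized 2D position histogram over cavity-interior bins.

    Pools all supplied trajectories (e.g. both channels, many clips).
    Positions falling outside the cavity are counted into the nearest grid
    cell and reported in ``meta['n_outside']`` rather than silently
    dropped.  Pass ``template`` (e.g. the mean-field grid) to histogram at
    a model grid's exact layout for later binning/comparison.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if template is None:
        if bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        template = make_grid(cavity, bin_size)
    pts = np.vstack([t.positions for t in trajs])
    from .geometry import contains
    n_outside = int((~contains(cavity, pts)).sum())

    dx = template.grid_spacing
    ix = np.clip(np.round((pts[:, 0] - template.origin[0]) / dx).astype(int),
                 0, template.shape[1] - 1)
    iy = np.clip(np.round((pts[:, 1] - template.origin[1]) / dx).astype(int),
                 0, template.shape[0] - 1)
    counts = np.zeros(template.shape)
    np.add.at(counts, (iy, ix), 1.0)
    counts[~template.mask] = 0.0
    out = template.copy_with(counts, role="probability").normalized()
    out.meta = {"n_outside": n_outside, "n_positions": len(pts)}
    return out


def free_energy_map(prob: ScalarField, floor_fraction: float = 0.5) -> ScalarField:
    """F = -log P in kBT, minimum shifted to zero.

    Thin alias of :func:`landscape_from_probability` — the histogram
    free-energy map and the BD landscape share one implementation.
    """
    return landscape_from_probability(prob, floor_fraction)


# ---------------------------------------------------------------------------
# separation vector / order parameter
# ---------------------------------------------------------------------------

def separation_series(traj1: Trajectory, traj2: Trajectory,
                      cavity: CavityGeometry) -> SeparationSeries:
    """Separation vector r = r1 - r2, its angle to the minor axis, and the
    major-axis projection normalized to the semi-major axis."""
    if len(traj1.positions) != len(traj2.positions) or \
            traj1.frame_interval != traj2.frame_interval:
        raise DataError("trajectories are on different time bases")
    r = traj1.positions - traj2.positions
    # angle between r and +y (minor axis), folded to [0, pi):
    # the separation is a director (r and -r equivalent)
    theta = np.mod(np.arctan2(r[:, 0], r[:, 1]), np.pi)
    proj = r[:, 0] / cavity.semi_major
    return SeparationSeries(
        times=traj1.times,
        separation_vectors=r,
        theta=theta,
        normalized_projection=proj,
        semi_major=cavity.semi_major,
    )


def order_parameter(thetas, convention: str = "major") -> float:
    """Alignment order parameter of the separation director.

    With phi the angle of the director to the **major** axis,
    S_align = 2 <cos^2 phi - 1/2>: 1 for perfect polar (major-axis)
    alignment, 0 for an isotropic angle distribution.  Since the stored
    theta is measured from the minor axis, phi = pi/2 - theta and
    S_align = 2 <sin^2 theta - 1/2>.

    ``convention="minor"`` returns the literal minor-axis form
    2 <cos^2 theta - 1/2>, which is -S_align.
    """
    th = np.asarray(thetas, dtype=float)
    if th.size == 0:
        raise DataError("empty angle sample")
    if convention == "major":
        return float(2.0 * (np.sin(th) ** 2 - 0.5).mean())
    if convention == "minor":
        return float(2.0 * (np.cos(th) ** 2 - 0.5).mean())
    raise ConfigurationError("convention must be 'major' or 'minor'")


# ---------------------------------------------------------------------------
# swap and dwell statistics
# ---------------------------------------------------------------------------

def detect_swaps(series: SeparationSeries, enter_threshold: float = 0.5,
                 exit_threshold: float = 0.25) -> tuple[DwellTimeStats, int]:
    """Two-state pole assignment with hysteresis on the projection series.

    State +1 is entered when the normalized projection exceeds
    +enter_threshold, state -1 below -enter_threshold; once assigned, the
    state is retained until the *opposite* enter threshold is crossed.
    Brief excursions that fail to cross the opposite threshold (the
    characteristic spike of a failed swap attempt) therefore do not count
    as swaps; excursions crossing the opposite ``exit_threshold`` but not
    the enter threshold are tallied as failed attempts in
    ``stats.extra['n_failed_attempts']``.

    Dwell time = time between successive state changes.  The first and
    last intervals are censored (reported separately, excluded from the
    samples).

    Returns (stats, swap_count).
    """
    if not (0.0 < exit_threshold < enter_threshold < 1.0):
        raise ConfigurationError("need 0 < exit_threshold < enter_threshold < 1")
    p = np.asarray(series.normalized_projection, dtype=float)
    dt = float(series.times[1] - series.times[0]) if len(series.times) > 1 else 1.0

    state = 0
    change_frames: list[int] = []
    first_assign: int | None = None
    n_failed = 0
    in_excursion = False
    for i, v in enumerate(p):
        new_state = state
        if v > enter_threshold:
            new_state = 1
        elif v < -enter_threshold:
            new_state = -1
        if state != 0 and new_state == state:
            # failed-attempt bookkeeping: crossing the opposite exit band
            if -state * v > exit_threshold:
                if not in_excursion:
                    n_failed += 1
                    in_excursion = True
            else:
                in_excursion = False
        if new_state != state:
            in_excursion = False
            if state == 0:
                first_assign = i
            else:
                change_frames.append(i)
            state = new_state
    if state == 0:
        stats = DwellTimeStats(dwell_samples=np.empty(0), n_events=0,
                               extra={"warning": "series never entered either state",
                                      "n_failed_attempts": 0})
        return stats, 0

    swap_count = len(change_frames)
    if swap_count >= 2:
        dwells = np.diff(change_frames) * dt
    else:
        dwells = np.empty(0)
    censored_first = (change_frames[0] - (first_assign or 0)) * dt if change_frames else None
    censored_last = (len(p) - 1 - change_frames[-1]) * dt if change_frames else None
    stats = DwellTimeStats(
        dwell_samples=dwells[dwells > 0],
        n_events=0,  # recomputed in __post_init__
        censored_first=censored_first,
        censored_last=censored_last,
        extra={"n_failed_attempts": n_failed},
    )
    return stats, swap_count


def fit_exponential_dwell(stats: DwellTimeStats) -> float:
    """Fit a single-exponential dwell law via the empirical survival curve.

    Least squares on log S(t) against t over the observed dwells; the
    negative inverse slope is tau.  The sample mean and an R^2 quality flag
    are reported alongside (a perfectly exponential sample has both close
    to tau).
    """
    t = np.sort(stats.dwell_samples)
    if len(t) < 5:
        raise FitError(f"need >= 5 uncensored dwells, have {len(t)}")
    if np.ptp(t) <= 1e-12 * t.mean():
        raise FitError("all dwell samples identical; survival curve degenerate")
    # survival just *before* each ordered dwell avoids log(0) at the last point
    n = len(t)
    surv = 1.0 - np.arange(n) / n
    log_s = np.log(surv)
    slope, intercept = np.polyfit(t, log_s, 1)
    if slope >= 0:
        raise FitError("non-decaying survival curve")
    tau = -1.0 / slope
    pred = slope * t + intercept
    ss_res = float(((log_s - pred) ** 2).sum())
    ss_tot = float(((log_s - log_s.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    stats.tau = float(tau)
    stats.extra.update(sample_mean=float(t.mean()), r_squared=r2,
                       poor_fit=bool(r2 < 0.9))
    return float(tau)


def pole_dwell_times(traj: Trajectory, l: float | None = None) -> DwellTimeStats:
    """Dwell times of a single molecule in the pole regions |x| > l/3.

    ``l`` is the maximum major-axis extension; by default the observed
    max |x| of the trajectory.  Contiguous pole visits must be
    sign-consistent: a run crossing directly from one pole to the other is
    split at the sign change.  Runs touching the start or end of the series
    are censored.
    """
    x = traj.x
    if l is None:
        l = float(np.abs(x).max())
    if l <= 0:
        raise DataError("maximum extension l must be positive")
    dt = traj.frame_interval
    region = np.where(np.abs(x) > l / 3.0, np.sign(x), 0.0)

    dwells = []
    censored_first = censored_last = None
    run_state = region[0]
    run_start = 0
    for i in range(1, len(region) + 1):
        s = region[i] if i < len(region) else None
        if s != run_state:
            if run_state != 0:
                duration = (i - run_start) * dt
                if run_start == 0:
                    censored_first = duration
                elif i == len(region):
                    censored_last = duration
                else:
                    dwells.append(duration)
            run_state = s
            run_start = i
    return DwellTimeStats(
        dwell_samples=np.array(dwells), n_events=0,
        censored_first=censored_first, censored_last=censored_last,
        extra={"l": l},
    )


def _mixture_nll(t: np.ndarray, w: float, tau1: float, tau2: float) -> float:
    pdf = w / tau1 * np.exp(-t / tau1) + (1 - w) / tau2 * np.exp(-t / tau2)
    return float(-np.log(np.maximum(pdf, 1e-300)).sum())


def fit_double_exponential(stats: DwellTimeStats, max_iter: int = 2000,
                           tol: float = 1e-10) -> tuple[float, float, float]:
    """Two-component exponential-mixture fit by EM maximum likelihood.

    Returns (tau_long, tau_short, weight_long).  Falls back to a
    single-exponential description (tau_long = tau_short = mean, flagged in
    ``stats.extra``) if EM degenerates.  Log-likelihoods of both the
    mixture and the nested single-exponential model are reported.
    """
    t = stats.dwell_samples
    if len(t) < 20:
        raise FitError(f"need >= 20 events for a mixture fit, have {len(t)}")
    mean = float(t.mean())
    # moment-flavoured initialization: split below/above the mean
    tau1 = float(t[t >= mean].mean()) if np.any(t >= mean) else 2 * mean
    tau2 = float(t[t < mean].mean()) if np.any(t < mean) else 0.5 * mean
    w = 0.5
    ok = True
    for _ in range(max_iter):
        p1 = w / tau1 * np.exp(-t / tau1)
        p2 = (1 - w) / tau2 * np.exp(-t / tau2)
        denom = p1 + p2
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            ok = False
            break
        g = p1 / denom
        w_new = float(g.mean())
        if w_new in (0.0, 1.0):
            ok = False
            break
        tau1_new = float((g * t).sum() / g.sum())
        tau2_new = float(((1 - g) * t).sum() / (1 - g).sum())
        delta = max(abs(w_new - w), abs(tau1_new - tau1) / tau1,
                    abs(tau2_new - tau2) / tau2)
        w, tau1, tau2 = w_new, tau1_new, tau2_new
        if delta < tol:
            break
    if not ok or min(tau1, tau2) <= 0:
        stats.extra["double_exponential_fallback"] = True
        stats.tau_long = stats.tau_short = mean
        stats.weight_long = 1.0
        return mean, mean, 1.0
    if tau1 < tau2:
        tau1, tau2, w = tau2, tau1, 1.0 - w
    stats.tau_long, stats.tau_short, stats.weight_long = tau1, tau2, w
    stats.extra.update(
        loglik_mixture=-_mixture_nll(t, w, tau1, tau2),
        loglik_single=-_mixture_nll(t, 1.0, mean, mean),
    )
    return float(tau1), float(tau2), float(w)


# ---------------------------------------------------------------------------
# mean-squared displacement
# ---------------------------------------------------------------------------

def msd_per_axis(traj: Trajectory, max_lag: float) -> MSDResult:
    """Time-averaged per-axis MSD up to ``max_lag`` seconds.

    MSD_par(tau) = < (x(t + tau) - x(t))^2 >_t along the major (x) axis,
    likewise MSD_perp along y.
    """
    dt = traj.frame_interval
    n = len(traj.positions)
    duration = (n - 1) * dt
    max_lag_frames = int(np.floor(max_lag / dt))
    truncated = False
    if max_lag >= duration:
        max_lag_frames = n - 1
        truncated = True
    max_lag_frames = max(1, min(max_lag_frames, n - 1))
    lags = dt * np.arange(1, max_lag_frames + 1)
    msd_x = np.empty(max_lag_frames)
    msd_y = np.empty(max_lag_frames)
    x, y = traj.x, traj.y
    for k in range(1, max_lag_frames + 1):
        dxs = x[k:] - x[:-k]
        dys = y[k:] - y[:-k]
        msd_x[k - 1] = np.mean(dxs**2)
        msd_y[k - 1] = np.mean(dys**2)
    out = MSDResult(lags=lags, msd_parallel=msd_x, msd_perpendicular=msd_y)
    if truncated:
        out.fit_window = None
    return out


def average_msd(results: list[MSDResult]) -> MSDResult:
    """Average MSD curves over clips (equal lag grids required)."""
    lags = results[0].lags
    for r in results[1:]:
        if len(r.lags) != len(lags) or not np.allclose(r.lags, lags):
            raise DataError("MSD results have different lag grids")
    return MSDResult(
        lags=lags,
        msd_parallel=np.mean([r.msd_parallel for r in results], axis=0),
        msd_perpendicular=np.mean([r.msd_perpendicular for r in results], axis=0),
    )


def fit_msd_exponent(msd: MSDResult, window: tuple[float, float] = (0.0, 1.0)
                     ) -> tuple[float, float]:
    """Power-law exponents alpha per axis from log-log regression.

    Fits log MSD against log lag over lags in ``window`` (default the
    short-time regime up to 1 s).  Returns (alpha_parallel,
    alpha_perpendicular); standard errors land on the result object.
    """
    lo, hi = window
    sel = (msd.lags > lo) & (msd.lags <= hi)
    if sel.sum() < 4:
        raise FitError("need >= 4 lags inside the fit window")

    def fit_axis(values: np.ndarray) -> tuple[float, float]:
        good = sel & (values > 0)
        if good.sum() < 2:
            raise FitError("all MSD values in the window are non-positive")
        lx = np.log(msd.lags[good])
        ly = np.log(values[good])
        coeffs, cov = np.polyfit(lx, ly, 1, cov=True)
        return float(coeffs[0]), float(np.sqrt(cov[0, 0]))

    a_par, se_par = fit_axis(msd.msd_parallel)
    a_perp, se_perp = fit_axis(msd.msd_perpendicular)
    msd.alpha_parallel, msd.alpha_parallel_stderr = a_par, se_par
    msd.alpha_perpendicular, msd.alpha_perpendicular_stderr = a_perp, se_perp
    msd.fit_window = window
    return a_par, a_perp


# ---------------------------------------------------------------------------
# crowding / density profiles
# ---------------------------------------------------------------------------

def contour_profile(prob: ScalarField, cavity: CavityGeometry,
                    mode: str = "elliptical", n_bins: int = 25) -> RadialProfile:
    """Mean probability density binned by a normalized radial coordinate.

    mode "radial": plain radius |r| normalized by the semi-major axis (for
    a circle, by its radius).  mode "elliptical": the effective radial
    coordinate r_eff = sqrt((x/A)^2 + (y/B)^2), which labels confocal
    elliptical contours.  Bins are uniform on [0, 1]; empty bins are NaN
    and flagged, never zero-filled.
    """
    if mode not in ("radial", "elliptical"):
        raise ConfigurationError("mode must be 'radial' or 'elliptical'")
    X, Y = prob.cell_centers()
    pts = np.stack([X, Y], axis=-1)
    if mode == "radial":
        coord = np.sqrt(X**2 + Y**2) / cavity.semi_major
        scale = cavity.semi_major
    else:
        coord = effective_radius(cavity, pts)
        # physical scale of one unit of r_eff: mean of the semi-axes
        scale = 0.5 * (cavity.semi_major + cavity.semi_minor)
    c = coord[prob.mask]
    v = prob.values[prob.mask]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(c, edges) - 1, 0, n_bins - 1)
    density = np.full(n_bins, np.nan)
    for i in range(n_bins):
        in_bin = idx == i
        if np.any(in_bin):
            density[i] = v[in_bin].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(
        bin_centers=centers, density=density, mode=mode,
        physical_scale=float(scale),
        flags={"empty_bins": int(np.isnan(density).sum())},
    )


def distribution_edge(profile: RadialProfile) -> float:
    """Normalized radius where the profile falls to 1/e of its maximum.

    Scans outward from the maximum and linearly interpolates the outermost
    crossing.  If the profile never falls below max/e the edge is reported
    as 1.0 with a flag.
    """
    d = profile.density
    valid = ~np.isnan(d)
    if not np.any(valid) or np.nanmax(d) <= 0:
        raise DataError("profile has no positive maximum")
    target = np.nanmax(d) / np.e
    i_max = int(np.nanargmax(d))
    xs = profile.bin_centers
    below = None
    for i in range(i_max + 1, len(d)):
        if np.isnan(d[i]):
            continue
        if d[i] <= target:
            below = i
            break
    if below is None:
        profile.flags["edge_not_reached"] = True
        return 1.0
    # previous valid bin above target
    prev = below - 1
    while prev > i_max and np.isnan(d[prev]):
        prev -= 1
    x0, y0 = xs[prev], d[prev]
    x1, y1 = xs[below], d[below]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - target) * (x1 - x0) / (y0 - y1))


def edge_shift(profile_a: RadialProfile, profile_b: RadialProfile) -> float:
    """Inward displacement of profile_b's 1/e edge relative to profile_a, um.

    Positive when b's edge sits further inside; the normalized shift is
    converted with the profiles' shared physical scale.
    """
    if profile_a.mode != profile_b.mode:
        raise DataError("profiles use different modes")
    if profile_a.physical_scale != profile_b.physical_scale:
        raise DataError("profiles have different physical scales")
    ea = distribution_edge(profile_a)
    eb = distribution_edge(profile_b)
    if profile_a.flags.get("edge_not_reached") or profile_b.flags.get("edge_not_reached"):
        raise DataError("one of the profiles has a flagged (unreached) edge")
    return float((ea - eb) * profile_a.physical_scale)
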