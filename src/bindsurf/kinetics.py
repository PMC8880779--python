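"""First-order fluorescence binding kinetics and one-site inhibition fits.

Complex formation between a dye-labeled ligand and its receptor is reported
by a first-order rise of the fluorescence,

    F(t) = Fmax - (Fmax - F0) * exp(-k * (t - lag)),   t >= lag,

and ligand exchange by unlabeled competitor by the mirrored first-order
decay toward Fmin, optionally preceded by a lag phase (~1 min in the
calbindin traces).  The primary fitter is the linearized log-regression the
field reports: ln(Fmax - F) (or ln(F - Fmin)) against t, slope = -k.  The
plateau is estimated from the tail of the trace and refined by a
self-consistency iteration so that truncated recordings do not bias k.

Inhibition titrations follow the one-site hyperbolic model

    Y = Y0 - Qmax * x / (IC50 + x),

fit by nonlinear least squares with an optional seeded residual bootstrap
for the IC50 confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DataError, FitError

LN2 = math.log(2.0)

#: Fraction of trailing samples used for the plateau estimate.
PLATEAU_FRACTION = 0.1
#: Log-transform mask: points within this multiple of the noise floor of the
#: plateau are excluded to avoid log-of-noise blowup.
NOISE_FLOOR_MULTIPLE = 3.0
#: ... and never closer to the plateau than this fraction of the amplitude,
#: which bounds the leverage of plateau-estimate error on the log slope.
RELATIVE_FLOOR = 0.01


@dataclass(frozen=True)
class KineticTrace:
    """A time–fluorescence recording (seconds, arbitrary units)."""

    time: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise DataError("time and fluorescence must be 1-D and equal length")
        if t.size < 10:
            raise DataError("trace needs at least 10 samples")
        if not np.all(np.diff(t) > 0):
            raise DataError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise DataError("trace contains missing or non-finite values")


@dataclass(frozen=True)
class AssociationFit:
    k: float  # s^-1
    f0: float
    fmax: float
    lag: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise FitError(f"non-positive rate constant: {self.k}")
        if self.fmax <= self.f0:
            raise FitError("fitted plateau does not exceed baseline")

    @property
    def half_time(self) -> float:
        return LN2 / self.k


@dataclass(frozen=True)
class DecayFit:
    k: float  # s^-1
    fstart: float
    fmin: float
    lag: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise FitError(f"non-positive rate constant: {self.k}")
        if self.fstart <= self.fmin:
            raise FitError("fitted start does not exceed floor")

    @property
    def half_time(self) -> float:
        return LN2 / self.k


@dataclass(frozen=True)
class InhibitionFit:
    y0: float  # % fluorescence increase without inhibitor
    qmax: float  # % maximal quench at inhibitor saturation
    ic50: float  # nM
    r_squared: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise FitError(f"non-positive IC50: {self.ic50}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y0 - self.qmax * x / (self.ic50 + x)


@dataclass(frozen=True)
class AffinitySummary:
    kon: float
    koff: float
    kon_over_koff: float
    t_half_formation: float
    t_half_dissociation: float
    half_time_ratio: float


def _masked_log_ols(
    t: np.ndarray, f: np.ndarray, sign: float, plateau: float, mask_floor: float
) -> tuple[float, float, float, int]:
    """Ordinary regression of ln(residual) on t over the usable window.

    ``sign`` is +1 for a rise (residual = plateau - F), -1 for a decay.
    Returns (k, intercept_at_t0, r_squared, n_used).
    """
    residual = sign * (plateau - f)
    usable = residual > mask_floor
    if usable.sum() < 5:
        raise DataError("fewer than 5 usable points after masking")
    res = stats.linregress(t[usable], np.log(residual[usable]))
    return float(-res.slope), float(res.intercept), float(res.rvalue**2), int(usable.sum())


def _irls_log_fit(
    t: np.ndarray,
    f: np.ndarray,
    sign: float,
    plateau: float,
    mask_floor: float,
    n_iter: int = 4,
) -> tuple[float, float, int]:
    """Iteratively reweighted linear fit of ln(residual) on t.

    The log transform makes the noise heteroscedastic (variance ~ sigma^2 /
    residual^2), so points are weighted by the squared *model* residual
    exp(-2 k t); using the model rather than the measured residual keeps
    the weights uncorrelated with the noise and the slope unbiased.
    Returns (k, intercept_at_t0, weighted_r_squared, n_used).
    """
    residual = sign * (plateau - f)
    usable = residual > mask_floor
    if usable.sum() < 5:
        raise DataError("fewer than 5 usable points after masking")
    tt = t[usable]
    yy = np.log(residual[usable])
    w = np.ones_like(yy)
    k, intercept, slope = 0.0, 0.0, 0.0
    for _ in range(n_iter):
        total = w.sum()
        tm = (w * tt).sum() / total
        ym = (w * yy).sum() / total
        var = (w * (tt - tm) ** 2).sum()
        if var <= 0:
            raise FitError("degenerate time window")
        slope = (w * (tt - tm) * (yy - ym)).sum() / var
        k = -slope
        intercept = ym - slope * tm
        if k <= 0:
            break
        w = np.exp(-2.0 * k * (tt - tt[0]))
    ss_res = float((w * (yy - (intercept + slope * tt)) ** 2).sum())
    ss_tot = float((w * (yy - (w * yy).sum() / w.sum()) ** 2).sum())
    r2w = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(k), float(intercept), float(r2w), int(usable.sum())


def _refine_plateau(
    t: np.ndarray,
    f: np.ndarray,
    sign: float,
    plateau0: float,
    k0: float,
    amplitude: float,
    noise_floor: float,
    n_tail: int,
    mask_floor: float,
) -> float:
    """Choose the plateau that maximizes the linearity of the log plot.

    The tail-mean plateau estimate is biased when the recording stops before
    the process completes; the residual trend it leaves behind curves the
    log plot.  The search bracket is the tail-mean estimate plus the
    predicted truncation deficit (from the initial rate) and the plateau's
    own statistical uncertainty, so noise cannot drag the plateau away.
    """
    def badness(p: float) -> float:
        try:
            _, _, r2w, _ = _irls_log_fit(t, f, sign, p, mask_floor)
        except (FitError, DataError):
            return 1.0
        return 1.0 - r2w

    t_tail = t[-n_tail:]
    sigma = noise_floor / math.sqrt(n_tail)
    plateau, k = plateau0, k0
    # The deficit estimate depends on k, which depends on the plateau, so
    # the bracket-and-search step is repeated with the improved rate.
    for _ in range(3):
        deficit = amplitude * float(
            np.mean(np.exp(-k * np.clip(t_tail - t[0], 0.0, None)))
        )
        deficit = min(2.0 * deficit, 0.5 * amplitude)
        inward = 3.0 * sigma + 1e-9 * amplitude
        outward = deficit + 3.0 * sigma + 1e-9 * amplitude
        lo, hi = plateau0 - inward, plateau0 + outward
        if sign < 0:
            lo, hi = plateau0 - outward, plateau0 + inward
        res = optimize.minimize_scalar(
            badness, bounds=(lo, hi), method="bounded", options={"xatol": 1e-11}
        )
        candidate = float(res.x)
        if badness(candidate) > badness(plateau):
            break
        plateau = candidate
        try:
            k_new, _, _, _ = _irls_log_fit(t, f, sign, plateau, mask_floor)
        except (FitError, DataError):
            break
        if k_new <= 0 or abs(k_new - k) < 1e-9 * k:
            k = max(k_new, k)
            break
        k = k_new
    return plateau


def _candidate_lags(trace: KineticTrace, lag: float | str) -> np.ndarray:
    if lag == "auto":
        t = trace.time
        cutoff = t[0] + (t[-1] - t[0]) / 3.0
        return t[t <= cutoff]
    return np.array([float(lag)])


def _fit_first_order(
    trace: KineticTrace, lag: float | str, direction: str
) -> tuple[float, float, float, float, float]:
    """Shared rise/decay machinery.

    Returns (k, plateau, start_level, chosen_lag, r_squared).
    """
    t, f = trace.time, trace.fluorescence
    n_tail = max(2, int(round(PLATEAU_FRACTION * t.size)))
    tail = f[-n_tail:]
    head = f[: max(2, n_tail)]
    plateau0 = float(tail.mean())
    initial = float(head.mean())
    sign = 1.0 if direction == "rise" else -1.0
    if direction == "rise" and plateau0 <= initial:
        raise FitError("no rise detected")
    if direction == "decay" and plateau0 >= initial:
        raise FitError("no decay detected")
    noise_floor = float(tail.std(ddof=1))
    amplitude = abs(plateau0 - initial)
    mask_floor = max(NOISE_FLOOR_MULTIPLE * noise_floor, RELATIVE_FLOOR * amplitude)

    lag_grid = _candidate_lags(trace, lag)
    candidates: list[tuple[float, float, float]] = []  # (lag, r2w, k)
    for q in lag_grid:
        window = t >= q
        if window.sum() < 5:
            continue
        try:
            k, _, r2w, n_used = _irls_log_fit(
                t[window], f[window], sign, plateau0, mask_floor
            )
        except (FitError, DataError):
            continue
        if k <= 0 or (n_used < 10 and lag_grid.size > 1):
            continue
        candidates.append((float(q), r2w, k))
    if not candidates:
        raise FitError(f"no {direction} detected")
    # A later lag can inflate r2 by chance on a shrinking window, so take
    # the earliest lag whose r2 is within a small fraction of the best
    # fit's distance to a perfect one, rather than the argmax itself.
    r2_max = max(r2w for _, r2w, _ in candidates)
    threshold = r2_max - 0.05 * (1.0 - r2_max) - 1e-9
    best_lag, _, best_k = min(
        (c for c in candidates if c[1] >= threshold), key=lambda c: c[0]
    )

    window = t >= best_lag
    plateau = _refine_plateau(
        t[window], f[window], sign, plateau0, best_k, amplitude,
        noise_floor if noise_floor > 0 else 0.0, n_tail, mask_floor,
    )
    try:
        k, intercept, _, _ = _irls_log_fit(t[window], f[window], sign, plateau, mask_floor)
        _, _, r2, _ = _masked_log_ols(t[window], f[window], sign, plateau, mask_floor)
    except DataError as exc:
        raise FitError(str(exc)) from exc
    if k <= 0:
        raise FitError(f"no {direction} detected")
    # intercept is ln(residual) extrapolated to t = 0; the pre-rise baseline
    # is the residual amplitude at the lag onset.
    start_level = plateau - sign * math.exp(intercept - k * best_lag)
    return k, plateau, start_level, best_lag, r2


def fit_association(trace: KineticTrace, lag: float | str = 0.0) -> AssociationFit:
    """Fit a first-order fluorescence rise.

    ``lag="auto"`` scans candidate lags at every sample time in the first
    third of the trace and keeps the earliest lag achieving the maximal
    r-squared of the linearized fit.
    """
    k, fmax, f0, chosen_lag, r2 = _fit_first_order(trace, lag, "rise")
    return AssociationFit(k=k, f0=f0, fmax=fmax, lag=chosen_lag, r_squared=r2)


def fit_decay(trace: KineticTrace, lag: float | str = 0.0) -> DecayFit:
    """Fit a first-order fluorescence decay (ligand exchange)."""
    k, fmin, fstart, chosen_lag, r2 = _fit_first_order(trace, lag, "decay")
    return DecayFit(k=k, fstart=fstart, fmin=fmin, lag=chosen_lag, r_squared=r2)


def time_to_half_rise(trace: KineticTrace) -> float:
    """First crossing of the half-amplitude level, linearly interpolated.

    The baseline is the first sample and the plateau the mean of the final
    tail; for a pure exponential with lag L and rate k this returns
    L + ln2/k.
    """
    t, f = trace.time, trace.fluorescence
    n_tail = max(2, int(round(PLATEAU_FRACTION * t.size)))
    fmax = float(f[-n_tail:].mean())
    f0 = float(f[0])
    if fmax <= f0:
        raise FitError("no rise detected")
    target = 0.5 * (f0 + fmax)
    above = f >= target
    if not above.any():
        raise FitError("trace never reaches half amplitude")
    idx = int(np.argmax(above))
    if idx == 0:
        return float(t[0])
    t0, t1 = t[idx - 1], t[idx]
    y0, y1 = f[idx - 1], f[idx]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def fit_ic50(
    concentrations: np.ndarray,
    responses: np.ndarray,
    *,
    bootstrap: int = 0,
    seed: int | None = None,
) -> InhibitionFit | tuple[InhibitionFit, tuple[float, float]]:
    """Fit the one-site hyperbolic inhibition model.

    Parameters
    ----------
    concentrations, responses:
        Inhibitor concentrations (nM, including a zero point) and the
        percent fluorescence increase at each.
    bootstrap:
        If > 0, also return a (2.5%, 97.5%) residual-bootstrap confidence
        interval on the IC50 with that many seeded resamples.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DataError("concentrations and responses must be 1-D, equal length")
    if x.size < 4:
        raise DataError("need at least 4 titration points")
    if not np.any(x == 0):
        raise DataError("titration must include a zero-concentration point")
    if np.any(x < 0):
        raise DataError("concentrations must be non-negative")
    span = y.max() - y.min()
    if span <= 1e-9 * max(1.0, abs(y.max())):
        raise FitError("no inhibition detected")

    def model(x, y0, qmax, ic50):
        return y0 - qmax * x / (ic50 + x)

    y0_init = float(y[x == 0].mean())
    qmax_init = max(y0_init - float(y.min()), 1e-6)
    half_level = y0_init - 0.5 * qmax_init
    nonzero = x > 0
    ic50_init = float(x[nonzero][np.argmin(np.abs(y[nonzero] - half_level))])
    ic50_init = max(ic50_init, 1e-6)

    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            y,
            p0=(y0_init, qmax_init, ic50_init),
            bounds=((-np.inf, 0.0, 1e-12), (np.inf, np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    fitted = model(x, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = InhibitionFit(
        y0=float(popt[0]), qmax=float(popt[1]), ic50=float(popt[2]), r_squared=r2
    )
    if bootstrap <= 0:
        return fit

    rng = np.random.default_rng(seed)
    residuals = y - fitted
    draws = []
    for _ in range(bootstrap):
        y_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        try:
            p_star, _ = optimize.curve_fit(
                model,
                x,
                y_star,
                p0=popt,
                bounds=((-np.inf, 0.0, 1e-12), (np.inf, np.inf, np.inf)),
                maxfev=20000,
            )
            draws.append(p_star[2])
        except RuntimeError:
            continue
    if not draws:
        raise FitError("bootstrap resampling never converged")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return fit, (float(lo), float(hi))


def summarize_affinity(
    assoc: AssociationFit,
    dec: DecayFit,
    formation_t50: float | None = None,
) -> AffinitySummary:
    """Combine a formation and an exchange fit into affinity descriptors.

    ``half_time_ratio`` uses the observed time-to-half-rise when supplied
    (it includes any lag phase), otherwise the formation fit's ln2/k.
    """
    t_form = formation_t50 if formation_t50 is not None else assoc.half_time
    return AffinitySummary(
        kon=assoc.k,
        koff=dec.k,
        kon_over_koff=assoc.k / dec.k,
        t_half_formation=t_form,
        t_half_dissociation=dec.half_time,
        half_time_ratio=t_form / dec.half_time,
    )


def relative_affinity_fold(a: AffinitySummary, b: AffinitySummary) -> float:
    """(koff/kon)_a divided by (koff/kon)_b — the fold weaker a binds."""
    return (a.koff / a.kon) / (b.koff / b.kon)
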