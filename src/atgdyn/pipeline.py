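"""Processing of quantified punctum time courses.

Raw single-punctum traces (10 s cadence, arbitrary fluorescence units)
are peak-synchronized, spline-assisted aligned, filtered for irregular
repeats, trimmed to a window with at least three repeats per frame, and
regularized against slow photobleaching-like signal decline. Peak/trough
trains, population summaries, diameter statistics and the peak-count vs
diameter correlation are extracted from the processed traces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_lsq_spline
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import pearsonr, shapiro
from scipy.stats import t as t_dist

from .simulate import TimeCourse

__all__ = [
    "PeakTrain",
    "PopulationSummary",
    "DiameterStats",
    "PrepareResult",
    "CorrelationResult",
    "synchronize_on_peak",
    "smooth_trace",
    "savgol_trace",
    "mitophagy_prepare",
    "regularize_decline",
    "summarize_population",
    "detect_peaks",
    "extract_first_peaks",
    "diameter_stats",
    "correlate_counts_diameters",
]

logger = logging.getLogger(__name__)

DEFAULT_IRREGULARITY_CFG = {
    "max_delay_cv": 1.5,  # coefficient of variation of inter-peak delays
    "max_missing_fraction": 0.2,
    "min_peaks": 1,
}


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


def synchronize_on_peak(traces: list[TimeCourse]) -> list[TimeCourse]:
    """Shift every trace so its global maximum sits at time 0.

    Ties are broken to the earliest frame. A flat trace has no peak and
    is rejected.
    """
    out = []
    for tc in traces:
        finite = tc.intensities[np.isfinite(tc.intensities)]
        if finite.max() == finite.min():
            raise ValueError(f"trace {tc.repeat_id!r} is flat: no peak to synchronize on")
        out.append(tc.shifted(-tc.peak_time))
    return out


# ---------------------------------------------------------------------------
# peak / trough trains
# ---------------------------------------------------------------------------


@dataclass
class PeakTrain:
    """Alternating maxima and troughs of an oscillatory trace."""

    upper_peaks: list[tuple[float, float]]
    troughs: list[tuple[float, float]]
    upper_delays: np.ndarray  # s, between successive upper peaks
    lower_delays: np.ndarray  # s, between successive troughs
    t_mean: float = np.nan  # s, mean of (peak time - preceding trough time)
    t_sd: float = np.nan

    @property
    def n_peaks(self) -> int:
        return len(self.upper_peaks)


def _refine_extremum(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-frame extremum position by parabolic interpolation around i."""
    if i == 0 or i == y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-15 * max(abs(y1), 1e-30):
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def detect_peaks(
    trace: TimeCourse,
    min_prominence: float | None = None,
    min_separation_s: float = 20.0,
    refine: bool = True,
) -> PeakTrain:
    """Extract the alternating peak/trough train of a regularized trace.

    Peaks need a prominence of at least 10% of the trace range by default
    and a separation of two frames; with ``refine`` their positions are
    interpolated to sub-frame precision by a local parabola. The time
    differences between each upper peak and its preceding trough estimate
    the per-cycle time-to-peak statistics feeding the mitophagy model.
    """
    y = trace.intensities
    t = trace.times
    rng_y = float(np.nanmax(y) - np.nanmin(y))
    if min_prominence is None:
        min_prominence = 0.1 * rng_y
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation_s / dt)))
    idx, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    if idx.size == 0:
        return PeakTrain([], [], np.empty(0), np.empty(0))
    if refine:
        peaks = [_refine_extremum(t, y, int(i)) for i in idx]
    else:
        peaks = [(float(t[i]), float(y[i])) for i in idx]
    # one trough before each peak: minimum between consecutive peaks and
    # between the trace start and the first peak
    trough_idx = []
    starts = np.concatenate(([0], idx[:-1]))
    for a, b in zip(starts, idx):
        if b > a:
            trough_idx.append(a + int(np.argmin(y[a : b + 1])))
    troughs = [(float(t[i]), float(y[i])) for i in trough_idx]
    peak_times = np.array([p[0] for p in peaks])
    trough_times = np.array([p[0] for p in troughs])
    rise = peak_times[: trough_times.size] - trough_times
    return PeakTrain(
        upper_peaks=peaks,
        troughs=troughs,
        upper_delays=np.diff(peak_times),
        lower_delays=np.diff(trough_times),
        t_mean=float(np.mean(rise)) if rise.size else np.nan,
        t_sd=float(np.std(rise, ddof=1)) if rise.size > 1 else np.nan,
    )


# ---------------------------------------------------------------------------
# mitophagy preparation pipeline
# ---------------------------------------------------------------------------


@dataclass
class PrepareResult:
    """Aligned, filtered, trimmed traces with a provenance log."""

    traces: list[TimeCourse]
    dropped: dict[str, str]
    shifts: dict[str, float]  # s, applied alignment shift per retained trace
    log: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


def _spline_smooth(tc: TimeCourse, df: int | None) -> np.ndarray:
    """Least-squares spline with roughly n/5 degrees of freedom."""
    n = len(tc)
    if df is None:
        df = max(4, n // 5)
    n_interior = max(df - 4, 1)
    t_int = np.linspace(tc.times[0], tc.times[-1], n_interior + 2)[1:-1]
    knots = np.concatenate(([tc.times[0]] * 4, t_int, [tc.times[-1]] * 4))
    try:
        spl = make_lsq_spline(tc.times, tc.intensities, knots, k=3)
        return np.asarray(spl(tc.times))
    except Exception:  # singular designs on degenerate traces
        return tc.intensities.copy()


def smooth_trace(tc: TimeCourse, df: int | None = None) -> TimeCourse:
    """Spline-smoothed copy of a trace (default ~n/5 degrees of freedom).

    Strong smoothing suited to alignment and irregularity screening; for
    peak localization on oscillatory traces prefer :func:`savgol_trace`,
    which preserves peak positions.
    """
    return TimeCourse(tc.times, np.clip(_spline_smooth(tc, df), 0.0, None), tc.condition, tc.repeat_id)


def savgol_trace(tc: TimeCourse, window: int = 7, order: int = 2) -> TimeCourse:
    """Light Savitzky-Golay denoising that keeps peak positions intact."""
    from scipy.signal import savgol_filter

    w = min(window, len(tc) if len(tc) % 2 else len(tc) - 1)
    if w <= order:
        return tc.copy()
    y = savgol_filter(tc.intensities, w, order)
    return TimeCourse(tc.times, np.clip(y, 0.0, None), tc.condition, tc.repeat_id)


def extract_first_peaks(traces: list[TimeCourse], smooth: bool = True) -> list[TimeCourse]:
    """Cut each trace at the trough after its first aggregation peak.

    Peak and trough positions are located on a denoised copy (the raw
    values are returned), and the cut traces are synchronized on the
    denoised peak position rounded to the frame grid; synchronizing on
    the raw argmax would select noise-inflated frames and bias the mean
    pulse toward an artificially fast initial decline.
    Traces without a detectable peak are skipped.
    """
    out = []
    for tc in traces:
        ref = savgol_trace(tc) if smooth else tc
        train = detect_peaks(ref)
        if train.n_peaks == 0:
            continue
        first_peak_t = train.upper_peaks[0][0]
        later_troughs = [t for t, _ in train.troughs if t > first_peak_t]
        if later_troughs:
            end = later_troughs[0]
        elif train.n_peaks > 1:
            end = train.upper_peaks[1][0]
        else:
            end = tc.times[-1]
        # cap at the first sustained upturn after the peak: if the next
        # peak went undetected the trough may sit cycles away, which
        # would leak the second rise into the "first peak" segment
        post = np.flatnonzero(ref.times > first_peak_t)
        if post.size >= 3:
            dv = np.diff(ref.intensities[post])
            rising = (dv[:-1] > 0) & (dv[1:] > 0)
            if rising.any():
                end = min(end, float(ref.times[post[int(np.argmax(rising))]]))
        sel = tc.times <= end + 1e-9
        if sel.sum() < 3:
            continue
        out.append(
            TimeCourse(tc.times[sel] - first_peak_t, tc.intensities[sel], tc.condition, tc.repeat_id)
        )
    if not out:
        raise ValueError("no trace contained a detectable first aggregation peak")
    return out


def _grid_index(tc: TimeCourse, t0: float, dt: float) -> np.ndarray:
    return np.round((tc.times - t0) / dt).astype(int)


def _xcorr_shift(row: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift of ``row`` maximizing correlation with ``ref``."""
    best_s, best_c = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        shifted = np.full_like(row, np.nan)
        if s >= 0:
            shifted[s:] = row[: row.size - s] if s else row
        else:
            shifted[:s] = row[-s:]
        ok = np.isfinite(shifted) & np.isfinite(ref)
        if ok.sum() < 5:
            continue
        a, b = shifted[ok], ref[ok]
        if a.std() == 0 or b.std() == 0:
            continue
        c = float(np.corrcoef(a, b)[0, 1])
        if c > best_c + 1e-12:
            best_c, best_s = c, s
    return best_s


def mitophagy_prepare(
    traces: list[TimeCourse],
    spline_df: int | None = None,
    irregularity_cfg: dict | None = None,
    min_repeats: int = 3,
    max_shift_frames: int = 5,
    max_iter: int = 10,
) -> PrepareResult:
    """Align, filter and trim oscillatory mitophagy traces.

    Pipeline order: spline-smooth -> iterative integer-frame
    cross-correlation alignment against the population mean -> restore
    the original (unsplined) values at the aligned positions -> drop
    irregular traces (no detectable peaks, inter-peak delay CV above the
    cutoff, or too many missing frames) -> trim to the time window where
    every frame has at least ``min_repeats`` repeats.
    """
    if len(traces) < min_repeats:
        raise ValueError(f"need at least {min_repeats} traces, got {len(traces)}")
    cfg = {**DEFAULT_IRREGULARITY_CFG, **(irregularity_cfg or {})}
    log = [f"input: {len(traces)} traces"]
    dt = float(np.median(np.diff(traces[0].times)))
    t0 = min(tc.times[0] for tc in traces)

    smoothed = [_spline_smooth(tc, spline_df) for tc in traces]
    log.append(f"splined {len(traces)} traces (df~n/5)")

    # common integer grid, NaN-padded
    idx0 = [_grid_index(tc, t0, dt) for tc in traces]
    width = max(ix[-1] for ix in idx0) + 1 + 2 * max_shift_frames
    off = max_shift_frames

    def to_row(vals, ix):
        row = np.full(width, np.nan)
        row[ix + off] = vals
        return row

    rows = np.vstack([to_row(v, ix) for v, ix in zip(smoothed, idx0)])
    shifts = np.zeros(len(traces), dtype=int)
    for it in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pad columns
            ref = np.nanmean(rows, axis=0)
        changed = False
        for i in range(rows.shape[0]):
            s = _xcorr_shift(rows[i], ref, max_shift_frames)
            # cap the cumulative shift: it must stay inside the NaN pad,
            # and a trace drifting further has latched onto wrong cycles
            s = int(np.clip(shifts[i] + s, -max_shift_frames, max_shift_frames)) - shifts[i]
            if s != 0:
                rows[i] = np.roll(rows[i], s)
                if s > 0:
                    rows[i, :s] = np.nan
                else:
                    rows[i, s:] = np.nan
                shifts[i] += s
                changed = True
        # remove the common mode: a uniform drift of every trace changes
        # nothing about their relative alignment but walks into the cap
        med = int(np.median(shifts))
        if med != 0:
            for i in range(rows.shape[0]):
                rows[i] = np.roll(rows[i], -med)
                if med > 0:
                    rows[i, -med:] = np.nan  # clear wrapped entries
                else:
                    rows[i, :-med] = np.nan
            shifts -= med
        if not changed:
            break
    log.append(f"alignment converged after {it + 1} iteration(s); shifts (frames): {shifts.tolist()}")

    # restore original values at aligned positions
    aligned: list[TimeCourse] = []
    for tc, ix, s in zip(traces, idx0, shifts):
        aligned.append(
            TimeCourse(t0 + (ix + s) * dt, tc.intensities.copy(), tc.condition, tc.repeat_id)
        )

    dropped: dict[str, str] = {}
    kept: list[TimeCourse] = []
    kept_shifts: dict[str, float] = {}
    for tc, s, sm in zip(aligned, shifts, smoothed):
        frac_missing = float(np.mean(~np.isfinite(tc.intensities)))
        if frac_missing > cfg["max_missing_fraction"]:
            dropped[tc.repeat_id] = f"{frac_missing:.0%} of frames missing"
            continue
        # peak screening on a lightly denoised copy: the alignment spline
        # is too stiff for short oscillatory traces and can erase peaks
        finite = np.isfinite(tc.intensities)
        filled = np.interp(tc.times, tc.times[finite], tc.intensities[finite])
        train = detect_peaks(savgol_trace(TimeCourse(tc.times, filled, tc.condition, tc.repeat_id)))
        if train.n_peaks < cfg["min_peaks"]:
            dropped[tc.repeat_id] = "no detectable aggregation peaks"
            continue
        if train.upper_delays.size >= 2:
            cv = float(np.std(train.upper_delays, ddof=1) / np.mean(train.upper_delays))
            if cv > cfg["max_delay_cv"]:
                dropped[tc.repeat_id] = f"inter-peak delay CV {cv:.2f} above {cfg['max_delay_cv']}"
                continue
        kept.append(tc)
        kept_shifts[tc.repeat_id] = float(s * dt)
    log.append(f"dropped {len(dropped)} irregular trace(s): {dropped}")
    if len(kept) < min_repeats:
        raise ValueError(
            f"only {len(kept)} traces survive irregularity filtering (need {min_repeats}); "
            f"dropped: {dropped}"
        )

    # trim to the window where >= min_repeats traces have data
    edges = np.arange(
        min(tc.times[0] for tc in kept), max(tc.times[-1] for tc in kept) + 0.5 * dt, dt
    )
    coverage = np.zeros(edges.size, dtype=int)
    for tc in kept:
        i = np.round((tc.times - edges[0]) / dt).astype(int)
        good = np.isfinite(tc.intensities)
        coverage[i[good]] += 1
    ok = np.where(coverage >= min_repeats)[0]
    if ok.size < 3:
        raise ValueError("trimmed window shorter than 3 frames")
    runs = np.split(ok, np.where(np.diff(ok) > 1)[0] + 1)
    run = max(runs, key=len)  # longest contiguous well-covered window
    if run.size < 3:
        raise ValueError("trimmed window shorter than 3 frames")
    lo_t, hi_t = edges[run[0]], edges[run[-1]]
    trimmed = []
    for tc in kept:
        sel = (tc.times >= lo_t - 1e-9) & (tc.times <= hi_t + 1e-9)
        if sel.sum() >= 3:
            trimmed.append(TimeCourse(tc.times[sel], tc.intensities[sel], tc.condition, tc.repeat_id))
        else:
            dropped[tc.repeat_id] = "fewer than 3 frames inside the trimmed window"
            kept_shifts.pop(tc.repeat_id, None)
    log.append(f"trimmed to [{lo_t:.0f}, {hi_t:.0f}] s; retained {len(trimmed)} traces")
    if len(trimmed) < min_repeats:
        raise ValueError(f"only {len(trimmed)} traces survive trimming (need {min_repeats})")
    return PrepareResult(traces=trimmed, dropped=dropped, shifts=kept_shifts, log=log)


# ---------------------------------------------------------------------------
# bleaching regularization
# ---------------------------------------------------------------------------


def regularize_decline(trace: TimeCourse) -> TimeCourse:
    """Remove a slow multiplicative signal decline (photobleaching-like).

    A decaying exponential is fitted to the trough envelope and divided
    out (normalized to 1 at the first frame). If no decline is present
    or the fit fails the trace is returned unchanged (with a warning for
    fit failures).
    """
    if len(trace) < 5:
        raise ValueError("regularization needs at least 5 frames")
    y = trace.intensities
    t = trace.times - trace.times[0]
    train = detect_peaks(trace)
    if len(train.troughs) >= 3:
        env_t = np.array([p[0] for p in train.troughs]) - trace.times[0]
        env_y = np.array([p[1] for p in train.troughs])
    else:  # single-pulse or flat traces: use a running-minimum envelope
        k = max(len(trace) // 10, 2)
        order = np.argsort(y)[: max(3, k)]
        env_t, env_y = t[np.sort(order)], y[np.sort(order)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (a, b), _ = curve_fit(
                lambda x, a, b: a * np.exp(-b * x),
                env_t,
                env_y,
                p0=(max(env_y[0], 1e-12), 1e-4),
                bounds=([0.0, 0.0], [np.inf, 1.0]),
                maxfev=5000,
            )
    except Exception as exc:
        warnings.warn(f"decline fit failed ({exc}); returning trace unchanged", RuntimeWarning)
        return trace.copy()
    if np.exp(b * t[-1]) < 1.1:
        # less than a 10% drop over the whole trace is envelope structure,
        # not photobleaching; correcting it would only add distortion
        return trace.copy()
    corrected = y * np.exp(b * t)
    return TimeCourse(trace.times, corrected, trace.condition, trace.repeat_id)


# ---------------------------------------------------------------------------
# population summary
# ---------------------------------------------------------------------------


@dataclass
class PopulationSummary:
    """Per-frame mean, 95% CI of the mean, and SD across repeats."""

    times: np.ndarray
    mean: np.ndarray
    ci95_halfwidth: np.ndarray
    sd: np.ndarray
    n_per_timepoint: np.ndarray

    def as_trace(self, condition: str = "mean") -> TimeCourse:
        return TimeCourse(self.times, self.mean, condition=condition, repeat_id="mean")


def summarize_population(traces: list[TimeCourse]) -> PopulationSummary:
    """Pointwise mean +- CI95 (t-distribution) +- SD over aligned traces."""
    if len(traces) < 2:
        raise ValueError("population summary needs at least 2 traces")
    dt = float(np.median(np.diff(traces[0].times)))
    t0 = min(tc.times[0] for tc in traces)
    t1 = max(tc.times[-1] for tc in traces)
    grid = np.arange(t0, t1 + 0.5 * dt, dt)
    stack = np.full((len(traces), grid.size), np.nan)
    for r, tc in enumerate(traces):
        i = np.round((tc.times - t0) / dt).astype(int)
        stack[r, i] = tc.intensities
    n = np.sum(np.isfinite(stack), axis=0)
    if np.any(n < 2):
        raise ValueError(
            f"some time points have fewer than 2 repeats (min {n.min()}); trim the traces first"
        )
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    ci = t_dist.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PopulationSummary(grid, mean, ci, sd, n)


# ---------------------------------------------------------------------------
# diameters and correlation
# ---------------------------------------------------------------------------


@dataclass
class DiameterStats:
    """Per-event mean diameters with population statistics (um)."""

    per_event_means: pd.Series
    mean: float
    sd: float
    shapiro_p: float


def diameter_stats(measurements: pd.DataFrame, min_measurements: int = 8) -> DiameterStats:
    """Summarize a measurements table (columns event_id, measurement_um).

    The per-event value is the arithmetic mean of its measurements;
    events with fewer than ``min_measurements`` raise.
    """
    counts = measurements.groupby("event_id")["measurement_um"].count()
    if (counts < min_measurements).any():
        bad = counts[counts < min_measurements]
        raise ValueError(f"events with fewer than {min_measurements} measurements: {dict(bad)}")
    per_event = measurements.groupby("event_id")["measurement_um"].mean()
    if (per_event <= 0).any():
        raise ValueError("per-event mean diameters must be positive")
    w, p = shapiro(per_event.to_numpy())
    return DiameterStats(
        per_event_means=per_event,
        mean=float(per_event.mean()),
        sd=float(per_event.std(ddof=1)),
        shapiro_p=float(p),
    )


@dataclass
class CorrelationResult:
    """Pearson correlation with a least-squares line and its CI band."""

    r: float
    p_value: float
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]

    def band(self, x: np.ndarray, _x_data=None):  # filled in by the fit
        raise NotImplementedError


def correlate_counts_diameters(peak_counts, diameters) -> CorrelationResult:
    """Pearson r (two-sided p) and OLS line for counts vs diameters."""
    x = np.asarray(diameters, dtype=float)
    y = np.asarray(peak_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equally sized samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in one of the samples")
    import statsmodels.api as sm

    r, p = pearsonr(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    res = CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
    )

    def band(xs: np.ndarray):
        xs = np.asarray(xs, dtype=float)
        pred = fit.get_prediction(sm.add_constant(xs)).conf_int(alpha=0.05)
        return pred[:, 0], pred[:, 1]

    res.band = band  # type: ignore[method-assign]
    return res
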