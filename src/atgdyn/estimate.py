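"""Parameter estimation, model selection and identifiability analysis.

Fitting follows the study protocol shape: many independent global
optimizer runs ("multi-start"), retention of the best 75% of starts,
AIC ranking across model variants, and profile-likelihood identifiability
at the 66/95/99% confidence levels. The global optimizer is differential
evolution; rate-like parameters are searched in log10 space.

The mitophagy model is calibrated in two stages: stage 1 fits the ATG13
kinetic rate constants on peak-synchronized first-aggregation data;
stage 2 fits the oscillation parameters (kprodLC3, kpeak, p) on the full
mean time course in two rounds, with the per-cycle time-to-peak and the
mitochondrial diameter fixed at their empirical means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize
from scipy.stats import chi2

from .models import MitophagyParams, ModelVariant, NonselectiveParams
from .simulate import (
    EngulfmentError,
    IntegrationError,
    TimeCourse,
    nonselective_curve,
    simulate_mitophagy,
)

__all__ = [
    "EstimationResult",
    "ProfileCurve",
    "DEFAULT_BOUNDS",
    "sse_objective",
    "fit_multistart",
    "compute_aic",
    "rank_variants",
    "profile_likelihood",
    "profile_objective",
    "fit_mitophagy_two_stage",
]

logger = logging.getLogger(__name__)

# search bounds; rates are explored on a log10 scale
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kprodATG13": (1e-6, 10.0),
    "kremATG13": (1e-6, 10.0),
    "m": (0.0, 4.0),
    "kwrtm": (1e-3, 1.0),
    "t": (10.0, 600.0),
    "kprodLC3": (1e-6, 10.0),
    "kpeak": (1e-3, 50.0),
    "p": (0.0, 6.0),
    "atg13_seed": (1e-4, 1.0),
}
_LOG_SCALE = {"kprodATG13", "kremATG13", "kprodLC3", "kpeak", "atg13_seed"}

DEFAULT_OPTIMIZER_CFG = {"iterations": 120, "swarm_size": 15}


def variant_param_names(variant: ModelVariant) -> list[str]:
    """Parameters estimated for a variant; eventless variants drop t."""
    names = ["kprodATG13", "kremATG13", "m", "kwrtm", "t"]
    return names if variant.event_based else names[:-1]


def is_wortmannin_condition(condition: str) -> bool:
    return "wortmannin" in condition.lower()


# ---------------------------------------------------------------------------
# parameter vector <-> search space transform
# ---------------------------------------------------------------------------


class _Transform:
    """Maps named parameters to the optimizer's search vector and back."""

    def __init__(self, names: list[str], bounds: dict[str, tuple[float, float]]):
        self.names = names
        self.lo = np.array(
            [np.log10(bounds[n][0]) if n in _LOG_SCALE else bounds[n][0] for n in names]
        )
        self.hi = np.array(
            [np.log10(bounds[n][1]) if n in _LOG_SCALE else bounds[n][1] for n in names]
        )
        for n in names:
            if not np.isfinite(bounds[n]).all() or bounds[n][0] >= bounds[n][1]:
                raise ValueError(f"invalid bounds for {n}: {bounds[n]}")

    @property
    def de_bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lo, self.hi))

    def to_named(self, x: np.ndarray) -> dict[str, float]:
        return {
            n: float(10.0**v if n in _LOG_SCALE else v) for n, v in zip(self.names, x)
        }

    def to_vector(self, named: dict[str, float]) -> np.ndarray:
        return np.array(
            [np.log10(named[n]) if n in _LOG_SCALE else named[n] for n in self.names]
        )


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def _as_trace_list(traces) -> list[TimeCourse]:
    return [traces] if isinstance(traces, TimeCourse) else list(traces)


def _dataset_offset(datasets: dict[str, list[TimeCourse]]) -> float:
    """Common shift placing the earliest synchronized frame at time 0."""
    tmin = min(tc.times[0] for traces in datasets.values() for tc in _as_trace_list(traces))
    return -float(tmin)


def sse_objective(
    params: NonselectiveParams,
    variant: ModelVariant,
    datasets: dict[str, list[TimeCourse]],
    offset: float | None = None,
) -> float:
    """Sum of squared residuals over all conditions and time points.

    ``datasets`` maps condition labels to synchronized traces; a condition
    whose label contains "wortmannin" is simulated with the wortmannin
    factor active. Traces synchronized on the peak (time 0 at the
    maximum) are placed on the simulation axis by one common offset so
    that the earliest frame sits at time 0. Integration failures yield
    +inf rather than raising.
    """
    if offset is None:
        offset = _dataset_offset(datasets)
    ssr = 0.0
    for condition, traces in datasets.items():
        wtm = is_wortmannin_condition(condition)
        for tc in _as_trace_list(traces):
            times = tc.times + offset
            keep = times >= 0
            try:
                sim = nonselective_curve(times[keep], params, variant, wortmannin=wtm)
            except IntegrationError:
                return np.inf
            resid = sim - tc.intensities[keep]
            if not np.all(np.isfinite(resid)):
                return np.inf
            ssr += float(resid @ resid)
    return ssr


def _count_residuals(datasets: dict[str, list[TimeCourse]]) -> int:
    return sum(len(tc) for traces in datasets.values() for tc in _as_trace_list(traces))


# ---------------------------------------------------------------------------
# multi-start global estimation
# ---------------------------------------------------------------------------


@dataclass
class EstimationResult:
    """Outcome of a multi-start fit.

    ``starts`` holds every (named-parameter dict, objective) pair;
    ``retained`` the best-75% subset used for downstream analysis.
    """

    best_params: NonselectiveParams | MitophagyParams
    objective: float
    starts: list[tuple[dict[str, float], float]]
    retained: list[tuple[dict[str, float], float]]
    n_data: int
    n_params: int
    aic: float = np.nan
    variant: ModelVariant | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isnan(self.aic):
            self.aic = compute_aic(self)


def _retain_best(starts: list[tuple[dict, float]]) -> list[tuple[dict, float]]:
    n_keep = max(1, int(np.floor(0.75 * len(starts))))
    return sorted(starts, key=lambda s: s[1])[:n_keep]


def _run_de(func, bounds, seed, cfg, x0=None) -> tuple[np.ndarray, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = differential_evolution(
            func,
            bounds,
            maxiter=cfg["iterations"],
            popsize=cfg["swarm_size"],
            tol=1e-10,
            seed=seed,
            polish=True,
            init="latinhypercube",
            x0=x0,
        )
    return res.x, float(res.fun)


def fit_multistart(
    variant: ModelVariant,
    datasets: dict[str, list[TimeCourse]],
    n_starts: int = 50,
    optimizer_cfg: dict | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    base_params: NonselectiveParams | None = None,
    fit_seed: bool = False,
) -> EstimationResult:
    """Fit a nonselective variant by repeated global optimization.

    Runs ``n_starts`` independently seeded differential-evolution
    searches, retains the best 75%, and reports the overall best
    parameter set with its AIC. ``fixed`` pins named parameters (they
    are excluded from the search and from the AIC parameter count);
    ``fit_seed`` adds the initial amount atg13_seed as a fitted nuisance
    parameter (useful when fitting population means, whose effective
    initial amount exceeds the single-trace seed).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    cfg = {**DEFAULT_OPTIMIZER_CFG, **(optimizer_cfg or {})}
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    fixed = fixed or {}
    base = base_params or NonselectiveParams()
    names = [n for n in variant_param_names(variant) if n not in fixed]
    if fit_seed and "atg13_seed" not in fixed:
        names.append("atg13_seed")
    if not names:
        raise ValueError("no free parameters to estimate")
    tr = _Transform(names, bnds)
    offset = _dataset_offset(datasets)

    def func(x: np.ndarray) -> float:
        named = tr.to_named(x)
        p = base.replace(**fixed, **named)
        return sse_objective(p, variant, datasets, offset=offset)

    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    starts: list[tuple[dict, float]] = []
    for s in seeds:
        x, f = _run_de(func, tr.de_bounds, np.random.default_rng(s), cfg)
        starts.append((tr.to_named(x), f))
    finite = [s for s in starts if np.isfinite(s[1])]
    if not finite:
        raise RuntimeError(
            f"all {n_starts} starts diverged for variant {variant.variant_id}; "
            f"objectives: {[s[1] for s in starts]}"
        )
    best_named, best_obj = min(finite, key=lambda s: s[1])
    return EstimationResult(
        best_params=base.replace(**fixed, **best_named),
        objective=best_obj,
        starts=starts,
        retained=_retain_best(starts),
        n_data=_count_residuals(datasets),
        n_params=len(names),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def compute_aic(result: EstimationResult) -> float:
    """AIC under Gaussian residuals: n*ln(SSR/n) + 2k.

    Only AIC differences between variants fitted to the same data are
    meaningful. A zero SSR returns -inf with a warning.
    """
    n, k, ssr = result.n_data, result.n_params, result.objective
    if n <= k:
        raise ValueError(f"need more residuals ({n}) than parameters ({k})")
    if ssr <= 0.0:
        warnings.warn("objective is 0; AIC degenerates to -inf", RuntimeWarning)
        return -np.inf
    return float(n * np.log(ssr / n) + 2 * k)


def rank_variants(results: list[EstimationResult]) -> list[EstimationResult]:
    """Order fitted variants by ascending AIC (best first)."""
    return sorted(results, key=lambda r: r.aic)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------


@dataclass
class ProfileCurve:
    """Profile-likelihood scan of one parameter.

    Confidence intervals collect the connected region around the best fit
    where the re-optimized objective stays below
    SSR_min * exp(chi2_1(alpha) / n); an interval end that runs into the
    search bound is flagged open (non-identifiable on that side).
    """

    param_name: str
    grid: np.ndarray
    objectives: np.ndarray
    best_value: float
    best_objective: float
    n_data: int
    ci: dict[float, tuple[float, float, bool, bool]] = field(default_factory=dict)

    def interval(self, level: float) -> tuple[float, float, bool, bool]:
        return self.ci[level]

    @property
    def identifiable(self) -> dict[float, bool]:
        return {lvl: not (lo_open or hi_open) for lvl, (_, _, lo_open, hi_open) in self.ci.items()}


def _threshold(ssr_min: float, n: int, level: float) -> float:
    """Objective bound for a confidence level (likelihood-ratio form)."""
    return ssr_min * float(np.exp(chi2.ppf(level, df=1) / n))


def _ci_from_profile(
    grid: np.ndarray, objs: np.ndarray, best_value: float, bound: float
) -> tuple[float, float, bool, bool]:
    """Connected sub-threshold interval around the best value."""
    below = objs <= bound
    i_best = int(np.argmin(np.abs(grid - best_value)))
    if not below[i_best]:
        below[i_best] = True  # numeric safety: the minimum defines the curve
    lo_i = i_best
    while lo_i > 0 and below[lo_i - 1]:
        lo_i -= 1
    hi_i = i_best
    while hi_i < grid.size - 1 and below[hi_i + 1]:
        hi_i += 1
    # interpolate the crossing just outside the plateau
    if lo_i > 0:
        x0, x1, y0, y1 = grid[lo_i - 1], grid[lo_i], objs[lo_i - 1], objs[lo_i]
        lo = x1 + (x0 - x1) * (bound - y1) / (y0 - y1) if y0 != y1 else x0
        lo_open = False
    else:
        lo, lo_open = float(grid[0]), True
    if hi_i < grid.size - 1:
        x0, x1, y0, y1 = grid[hi_i], grid[hi_i + 1], objs[hi_i], objs[hi_i + 1]
        hi = x0 + (x1 - x0) * (bound - y0) / (y1 - y0) if y0 != y1 else x1
        hi_open = False
    else:
        hi, hi_open = float(grid[-1]), True
    return float(lo), float(hi), lo_open, hi_open


def profile_objective(
    reoptimize,
    grid: np.ndarray,
    best_value: float,
    best_objective: float,
    n_data: int,
    param_name: str = "theta",
    levels: tuple[float, ...] = (0.66, 0.95, 0.99),
) -> ProfileCurve:
    """Generic profile builder from a ``reoptimize(fixed_value)`` callable.

    ``reoptimize`` must return the objective minimized over all other
    parameters with the profiled one held at ``fixed_value``. Used both
    by :func:`profile_likelihood` and directly for models with an
    analytic or custom objective.
    """
    objs = np.array([float(reoptimize(v)) for v in grid])
    curve = ProfileCurve(
        param_name=param_name,
        grid=np.asarray(grid, dtype=float),
        objectives=objs,
        best_value=float(best_value),
        best_objective=float(best_objective),
        n_data=n_data,
    )
    ssr_min = min(best_objective, float(np.nanmin(objs)))
    for lvl in levels:
        curve.ci[lvl] = _ci_from_profile(curve.grid, objs, best_value, _threshold(ssr_min, n_data, lvl))
    return curve


def profile_likelihood(
    param_name: str,
    result: EstimationResult,
    variant: ModelVariant,
    datasets: dict[str, list[TimeCourse]],
    levels: tuple[float, ...] = (0.66, 0.95, 0.99),
    grid_size: int = 41,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: dict[str, float] | None = None,
) -> ProfileCurve:
    """Profile one parameter of a fitted nonselective variant.

    The parameter is scanned over its bounds (log-spaced when its lower
    bound is positive and rate-like, linear otherwise); at each grid
    value all other free parameters are re-optimized by warm-started
    local search marching outward from the best fit.
    """
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    fixed = fixed or {}
    if param_name in fixed:
        raise ValueError(f"cannot profile fixed parameter {param_name}")
    names = [n for n in variant_param_names(variant) if n not in fixed]
    if param_name not in names:
        raise ValueError(f"{param_name} is not estimated for variant {variant.variant_id}")
    lo, hi = bnds[param_name]
    best = result.best_params
    best_val = float(getattr(best, param_name))
    if not (lo <= best_val <= hi):
        raise ValueError(f"best-fit {param_name}={best_val} outside grid bounds {bnds[param_name]}")
    if param_name in _LOG_SCALE:
        grid = np.geomspace(lo, hi, grid_size)
    else:
        grid = np.linspace(lo, hi, grid_size)
    others = [n for n in names if n != param_name]
    tr = _Transform(others, bnds) if others else None
    offset = _dataset_offset(datasets)
    base = best if isinstance(best, NonselectiveParams) else NonselectiveParams()

    def reopt_from(x0: np.ndarray | None, fixed_value: float) -> tuple[float, np.ndarray | None]:
        pin = {**fixed, param_name: fixed_value}
        if tr is None:
            return sse_objective(base.replace(**pin), variant, datasets, offset=offset), None

        def func(x):
            p = base.replace(**pin, **tr.to_named(x))
            return sse_objective(p, variant, datasets, offset=offset)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                func,
                x0,
                method="Nelder-Mead",
                bounds=tr.de_bounds,
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
        return float(res.fun), res.x

    objs = np.full(grid.size, np.nan)
    i_best = int(np.argmin(np.abs(grid - best_val)))
    x_start = tr.to_vector({n: float(getattr(best, n)) for n in others}) if tr else None
    # march outward in both directions, warm-starting from the neighbor
    for idxs in (range(i_best, -1, -1), range(i_best, grid.size)):
        x0 = None if x_start is None else x_start.copy()
        for i in idxs:
            if np.isfinite(objs[i]):
                continue
            objs[i], x_sol = reopt_from(x0, float(grid[i]))
            if x_sol is not None:
                x0 = x_sol
    curve = ProfileCurve(
        param_name=param_name,
        grid=grid,
        objectives=objs,
        best_value=best_val,
        best_objective=result.objective,
        n_data=result.n_data,
    )
    ssr_min = min(result.objective, float(np.nanmin(objs)))
    for lvl in levels:
        curve.ci[lvl] = _ci_from_profile(grid, objs, best_val, _threshold(ssr_min, result.n_data, lvl))
    return curve


# ---------------------------------------------------------------------------
# two-stage mitophagy calibration
# ---------------------------------------------------------------------------


def mean_trace(
    traces: list[TimeCourse], condition: str = "mean", min_coverage: float = 0.5
) -> TimeCourse:
    """Pointwise mean over aligned traces.

    Frames covered by fewer than ``min_coverage`` of the traces (at least
    2) are discarded, and the longest contiguous well-covered run is
    returned; a strict intersection would let a single short repeat
    truncate the window.
    """
    traces = _as_trace_list(traces)
    step = float(np.median(np.diff(traces[0].times)))
    lo = min(tc.times[0] for tc in traces)
    hi = max(tc.times[-1] for tc in traces)
    grid = np.arange(lo, hi + 0.5 * step, step)
    stack = np.full((len(traces), grid.size), np.nan)
    for r, tc in enumerate(traces):
        i = np.round((tc.times - lo) / step).astype(int)
        ok = (i >= 0) & (i < grid.size)
        stack[r, i[ok]] = tc.intensities[ok]
    count = np.sum(np.isfinite(stack), axis=0)
    need = max(2, int(np.ceil(min_coverage * len(traces)))) if len(traces) > 1 else 1
    good = count >= need
    if not good.any():
        raise ValueError("traces share no sufficiently covered time window")
    # longest contiguous well-covered run
    runs = np.split(np.flatnonzero(good), np.where(np.diff(np.flatnonzero(good)) > 1)[0] + 1)
    run = max(runs, key=len)
    if run.size < 3:
        raise ValueError("covered time window shorter than 3 frames")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack[:, run], axis=0)
    return TimeCourse(grid[run], mean, condition=condition, repeat_id="mean")


def _stage1_joint_objective(
    kprod: float,
    krem: float,
    traces: list[TimeCourse],
    base: MitophagyParams,
) -> float:
    """Joint SSE of peak-synchronized first-aggregation traces.

    Each trace is compared against a pulse with the event time set to its
    own observed rise duration (trace start to synchronized peak), so no
    cross-trace averaging or alignment smear enters the kinetics.
    Residuals are taken in log space, matching the multiplicative noise
    of fluorescence intensities. The argmax frame itself is excluded:
    under noise the synchronized maximum is a noise-selected order
    statistic and sits systematically above the curve.
    """
    ssr = 0.0
    variant = ModelVariant(3)
    for tc in traces:
        t_i = -float(tc.times[0])
        if t_i <= 0:
            continue
        p = NonselectiveParams(
            kprodATG13=kprod,
            kremATG13=krem,
            m=base.m,
            kwrtm=1.0,
            t=t_i,
            atg13_seed=base.atg13_seed,
            removal_order_m=base.removal_order_m,
        )
        times = tc.times + t_i  # pulse axis: trace start at 0, event at t_i
        try:
            sim = nonselective_curve(times, p, variant)
        except IntegrationError:
            return np.inf
        # the punctum signal rests at the seed level between cycles; the
        # observable never falls below it, so neither should the model
        sim = np.maximum(sim, base.atg13_seed)
        ok = (tc.intensities > 0) & (sim > 0)
        i_peak = int(np.argmin(np.abs(tc.times)))
        ok[i_peak] = False
        if ok.sum() < 3:
            continue
        resid = np.log(sim[ok]) - np.log(tc.intensities[ok])
        if not np.all(np.isfinite(resid)):
            return np.inf
        ssr += float(resid @ resid)
    return ssr


_PEAK_TIME_SCALE = 3.0  # s, ~sub-frame peak localization accuracy
_PEAK_COUNT_PENALTY = 100.0
# prior widths of the nuisance drift absorbing stage-1 timing error:
# a few-percent error in the fixed kinetic rates shifts every cycle's
# active duration by ~1-2 s, which accumulates linearly in the peak
# positions and would otherwise be soaked up by the delay exponent
_DRIFT_OFFSET_SD = 3.0  # s, absolute synchronization offset
_DRIFT_SLOPE_SD = 2.0  # s per cycle, active-duration mismatch


def _drift_adjusted_position_ssr(resid: np.ndarray) -> float:
    """Position SSR with a ridge-regularized affine drift removed.

    Solves min over (offset, slope) of
    sum(((resid - offset - slope*k) / scale)^2) + (offset/sd0)^2 +
    (slope/sd1)^2; the priors keep genuine delay-growth signal (which is
    convex in the cycle index) from leaking into the nuisance.
    """
    n = resid.size
    k = np.arange(n, dtype=float)
    s2 = _PEAK_TIME_SCALE**2
    X = np.column_stack([np.ones(n), k])
    A = X.T @ X / s2 + np.diag([1.0 / _DRIFT_OFFSET_SD**2, 1.0 / _DRIFT_SLOPE_SD**2])
    beta = np.linalg.solve(A, X.T @ resid / s2)
    adj = resid - X @ beta
    return float(
        np.sum((adj / _PEAK_TIME_SCALE) ** 2)
        + (beta[0] / _DRIFT_OFFSET_SD) ** 2
        + (beta[1] / _DRIFT_SLOPE_SD) ** 2
    )


def _mitophagy_stage2_objective(
    params: MitophagyParams,
    data: TimeCourse,
    data_peaks: np.ndarray,
    trace_scale: float,
) -> float:
    """Trace SSR plus a peak-position term for the deterministic model.

    The positions of the aggregation peaks carry most of the information
    on (kpeak, p): they accumulate the growing inter-cycle delays, so a
    wrong exponent displaces late peaks by far more than the frame
    interval. Position residuals are scaled to frames; a mismatch in
    peak count is penalized heavily.
    """
    det = params.replace(t_sd=0.0, mt_diam_sd=0.0)
    try:
        sim = simulate_mitophagy(det, seed=0, max_time=float(data.times[-1]) + 2 * det.t_mean)
    except (EngulfmentError, IntegrationError):
        return np.inf
    y = np.interp(data.times, sim.trace.times, sim.trace.intensities)
    ssr = float(np.sum((y - data.intensities) ** 2)) / trace_scale
    sim_peaks = sim.peak_times[sim.peak_times <= data.times[-1] + _PEAK_TIME_SCALE]
    k = min(sim_peaks.size, data_peaks.size)
    ssr += _PEAK_COUNT_PENALTY * abs(sim_peaks.size - data_peaks.size)
    if not sim.completed:
        # the recorded time course covers the whole mitophagy event, so a
        # parameterization whose engulfment never finishes is wrong even
        # if its peak positions happen to line up
        ssr += _PEAK_COUNT_PENALTY
    if k > 0:
        ssr += _drift_adjusted_position_ssr(data_peaks[:k] - sim_peaks[:k]) / k
    return ssr


def _delay_regression_init(
    data_peaks: np.ndarray, active_duration: float
) -> tuple[float, float] | None:
    """Rough (kpeak, p) from a log-log fit of detected inter-peak delays.

    Each observed inter-peak interval is the cycle active duration plus
    the programmed delay kpeak * k**p; subtracting the model-implied
    active duration and regressing log-delay on log-cycle-index gives a
    starting point that puts the global search in the right basin.
    """
    intervals = np.diff(data_peaks)
    delays = intervals - active_duration
    k = np.arange(1, delays.size + 1)
    ok = delays > 1e-3
    if ok.sum() < 2:
        return None
    slope, intercept = np.polyfit(np.log(k[ok]), np.log(delays[ok]), 1)
    p0 = float(np.clip(slope, 0.05, 5.95))
    kpeak0 = float(np.clip(np.exp(intercept), 2e-3, 45.0))
    return kpeak0, p0


def fit_mitophagy_two_stage(
    first_peak_traces: list[TimeCourse],
    full_traces: list[TimeCourse],
    t_stats: tuple[float, float],
    diam_stats: tuple[float, float],
    cfg: dict | None = None,
    seed: int = 0,
    base_params: MitophagyParams | None = None,
) -> EstimationResult:
    """Calibrate the mitophagy model in two stages.

    Stage 1 fits (kprodATG13, kremATG13) to the mean of the
    peak-synchronized first aggregations, with the time-to-peak fixed at
    its empirical mean. Stage 2 fits the oscillation parameters on the
    full mean time course with t and the mitochondrial diameter fixed at
    their means: round 1 estimates (kprodLC3, kpeak, p); round 2 fixes
    kprodLC3 (whose optimum lies on a plateau, being linked to the
    engulfment duration) and re-estimates the interdependent kpeak.

    ``t_stats`` and ``diam_stats`` are (mean, sd) pairs from the peak
    train and diameter analyses; both are required.
    """
    if t_stats is None or diam_stats is None:
        raise ValueError("t_stats and diam_stats (mean, sd) are required")
    t_mean, t_sd = float(t_stats[0]), float(t_stats[1])
    d_mean, d_sd = float(diam_stats[0]), float(diam_stats[1])
    if not (t_mean > 0 and d_mean > 0):
        raise ValueError("t and diameter means must be positive")
    cfg = {
        "n_starts_stage1": 8,
        "n_starts_stage2": 8,
        "optimizer_cfg": dict(DEFAULT_OPTIMIZER_CFG),
        "bounds": {},
        "smooth": True,
        **(cfg or {}),
    }
    base = base_params or MitophagyParams()
    base = base.replace(t_mean=t_mean, t_sd=t_sd, mt_diam_mean=d_mean, mt_diam_sd=d_sd)
    bnds = {**DEFAULT_BOUNDS, **cfg["bounds"]}

    from .pipeline import detect_peaks, savgol_trace  # local import to avoid a cycle

    # ---- stage 1: ATG13 kinetics on the first aggregation -----------------
    # joint fit over the synchronized first peaks, each against a pulse
    # with its own observed rise duration: averaging traces whose event
    # times differ would smear the peak and bias the rate constants
    obs_t = np.array([-tc.times[0] for tc in first_peak_traces])
    tol = 3.0 * max(t_sd, 5.0)
    keep1 = np.abs(obs_t - t_mean) <= tol
    if keep1.sum() >= max(3, len(first_peak_traces) // 2):
        # a rise far outside the time-to-peak distribution is a missed
        # first peak (detection latched onto a later cycle), not kinetics
        stage1_traces = [tc for tc, k in zip(first_peak_traces, keep1) if k]
    else:
        stage1_traces = list(first_peak_traces)
    names1 = ["kprodATG13", "kremATG13"]
    tr1 = _Transform(names1, bnds)

    def stage1_func(x: np.ndarray) -> float:
        named = tr1.to_named(x)
        return _stage1_joint_objective(
            named["kprodATG13"], named["kremATG13"], stage1_traces, base
        )

    seeds1 = np.random.SeedSequence(seed).spawn(cfg["n_starts_stage1"])
    starts1 = []
    for s in seeds1:
        x, f = _run_de(stage1_func, tr1.de_bounds, np.random.default_rng(s), cfg["optimizer_cfg"])
        starts1.append((tr1.to_named(x), f))
    finite1 = [s for s in starts1 if np.isfinite(s[1])]
    if not finite1:
        raise RuntimeError("all stage-1 starts diverged")
    best1, best1_obj = min(finite1, key=lambda s: s[1])
    kprod, krem = best1["kprodATG13"], best1["kremATG13"]
    n_data1 = sum(len(tc) for tc in stage1_traces)
    stage1 = EstimationResult(
        best_params=NonselectiveParams(
            kprodATG13=kprod, kremATG13=krem, m=base.m, kwrtm=1.0, t=t_mean,
            atg13_seed=base.atg13_seed,
        ),
        objective=best1_obj,
        starts=starts1,
        retained=_retain_best(starts1),
        n_data=n_data1,
        n_params=2,
    )
    base = base.replace(kprodATG13=kprod, kremATG13=krem)

    # ---- stage 2: oscillation parameters on the full mean trace ----------
    full_mean = mean_trace(full_traces, condition="mitophagy")
    # locate peaks on a lightly denoised copy (measurement noise otherwise
    # fakes aggregation peaks at the 10 s cadence); the trace residuals
    # are computed on the raw values, where the model is the smoother
    data_ref = savgol_trace(full_mean) if cfg["smooth"] else full_mean
    # aggregation peaks rise well above half the trace range; a permissive
    # prominence threshold would let residual noise wiggle in as peaks
    rng_y = float(np.max(data_ref.intensities) - np.min(data_ref.intensities))
    train = detect_peaks(data_ref, min_prominence=0.25 * rng_y)
    if len(train.upper_peaks) < 3 or train.upper_delays.size < 2:
        raise ValueError(
            "stage 2 needs at least 3 aggregation peaks (>= 2 inter-peak delays); "
            f"found {len(train.upper_peaks)} peaks"
        )
    # shift the data axis so the run starts at 0
    t0 = full_mean.times[0]
    data = TimeCourse(full_mean.times - t0, full_mean.intensities, full_mean.condition, "stage2")
    data_peaks = np.array([pt for pt, _ in train.upper_peaks]) - t0
    trace_scale = float(np.var(data.intensities)) * len(data) or 1.0

    names2 = ["kprodLC3", "kpeak", "p"]
    tr2 = _Transform(names2, bnds)

    def round1_func(x: np.ndarray) -> float:
        named = tr2.to_named(x)
        return _mitophagy_stage2_objective(
            base.replace(**named), data, data_peaks, trace_scale
        )

    # warm start: delay regression for (kpeak, p), LC3 budget for kprodLC3
    from .simulate import _decay, _grow  # closed-form pulse pieces

    a0 = base.atg13_seed
    a_peak = float(_grow(np.array([t_mean]), a0, kprod, base.m)[0])
    tau_rem = float(np.log(max(a_peak / (1.05 * a0), 1.001)) / krem) if krem > 0 else 0.0
    x0 = None
    init = _delay_regression_init(data_peaks, t_mean + tau_rem)
    if init is not None:
        int_a = (a_peak - a0) / max(kprod, 1e-12) + (a_peak - 1.05 * a0) / max(krem, 1e-12)
        lc3_guess = base.engulf_coeff * d_mean / max(data_peaks.size * int_a, 1e-12)
        x0 = tr2.to_vector(
            {
                "kprodLC3": float(np.clip(lc3_guess, 2e-6, 9.0)),
                "kpeak": init[0],
                "p": init[1],
            }
        )
    seeds = np.random.SeedSequence(seed + 1).spawn(cfg["n_starts_stage2"])
    starts = []
    for s in seeds:
        x, f = _run_de(
            round1_func, tr2.de_bounds, np.random.default_rng(s), cfg["optimizer_cfg"], x0=x0
        )
        starts.append((tr2.to_named(x), f))
    finite = [s for s in starts if np.isfinite(s[1])]
    if not finite:
        raise RuntimeError("all stage-2 round-1 starts diverged")
    round1_named, round1_obj = min(finite, key=lambda s: s[1])
    base = base.replace(**round1_named)

    # round 2: kprodLC3 (plateau) fixed, re-estimate kpeak alone
    tr_kpeak = _Transform(["kpeak"], bnds)

    def round2_func(x: np.ndarray) -> float:
        return _mitophagy_stage2_objective(
            base.replace(kpeak=tr_kpeak.to_named(x)["kpeak"]),
            data,
            data_peaks,
            trace_scale,
        )

    x2, round2_obj = _run_de(
        round2_func,
        tr_kpeak.de_bounds,
        np.random.default_rng(np.random.SeedSequence(seed + 2)),
        cfg["optimizer_cfg"],
    )
    best = base.replace(kpeak=tr_kpeak.to_named(x2)["kpeak"])
    return EstimationResult(
        best_params=best,
        objective=float(min(round1_obj, round2_obj)),
        starts=starts,
        retained=_retain_best(starts),
        n_data=len(data) + data_peaks.size,
        n_params=2 + len(names2),
        details={
            "stage1": stage1,
            "round1": {"params": round1_named, "objective": round1_obj},
            "round2": {"kpeak": best.kpeak, "objective": round2_obj},
            "t_stats": (t_mean, t_sd),
            "diam_stats": (d_mean, d_sd),
        },
    )
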