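"""Simulation of ATG13 punctum dynamics.

Two regimes are covered:

* the six nonselective single-pulse model variants, integrated either by
  their exact closed-form solutions (default; the rate laws are power-law
  /first-order and piecewise separable) or by an adaptive numeric
  integrator that splits the trajectory at the accumulation->removal
  event (cross-check route);
* the hybrid stochastic mitophagy model, a loop of aggregation cycles
  with per-cycle random time-to-peak, cumulative LC3 production, delays
  growing as ``kpeak * k**p`` and LC3-threshold termination set by the
  sampled mitochondrial fragment diameter.

All stochasticity flows through ``numpy.random.Generator`` seeded
explicitly, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import MitophagyParams, ModelVariant, NonselectiveParams, rate_accumulation, rate_removal

__all__ = [
    "TimeCourse",
    "Kymograph",
    "MitophagySimResult",
    "IntegrationError",
    "EngulfmentError",
    "nonselective_curve",
    "simulate_nonselective",
    "simulate_kymograph",
    "delay_for_cycle",
    "simulate_mitophagy",
    "simulate_mitophagy_population",
]

logger = logging.getLogger(__name__)

OUTPUT_DT = 10.0  # s, imaging cadence of the source movies


class IntegrationError(RuntimeError):
    """Trajectory became non-finite (finite-time blow-up for m > 1)."""


class EngulfmentError(RuntimeError):
    """The LC3 engulfment threshold can never be reached."""


# ---------------------------------------------------------------------------
# time-course container
# ---------------------------------------------------------------------------


@dataclass
class TimeCourse:
    """One punctum intensity trace: time in seconds, intensity in AU."""

    times: np.ndarray
    intensities: np.ndarray
    condition: str = "starvation"
    repeat_id: str = "0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if self.times.size < 3:
            raise ValueError("a time course needs at least 3 frames")
        if not np.all(np.isfinite(self.times)) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be finite and strictly increasing")
        finite = np.isfinite(self.intensities)
        if finite.sum() < 3:
            raise ValueError("a time course needs at least 3 finite intensities")
        if np.any(self.intensities[finite] < -1e-12):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    @property
    def peak_time(self) -> float:
        """Time of the global maximum (earliest frame on ties)."""
        finite = np.where(np.isfinite(self.intensities), self.intensities, -np.inf)
        return float(self.times[int(np.argmax(finite))])

    def shifted(self, dt: float) -> "TimeCourse":
        return TimeCourse(self.times + dt, self.intensities.copy(), self.condition, self.repeat_id)

    def copy(self) -> "TimeCourse":
        return TimeCourse(self.times.copy(), self.intensities.copy(), self.condition, self.repeat_id)


@dataclass
class Kymograph:
    """Stack of [0,1]-normalized repeats sorted by decreasing peak time."""

    matrix: np.ndarray  # n_repeats x n_timepoints
    row_order: list[str]
    times: np.ndarray
    peak_times: np.ndarray  # per sorted row, s
    n_resampled: int = 0


# ---------------------------------------------------------------------------
# closed-form nonselective solutions
# ---------------------------------------------------------------------------


def _grow(tau: np.ndarray, a0: float, c: float, m: float) -> np.ndarray:
    """Solution of dA/dt = c * A**m from A(0) = a0 on tau >= 0."""
    tau = np.asarray(tau, dtype=float)
    if c == 0.0:
        return np.full_like(tau, a0)
    if abs(m - 1.0) < 1e-12:
        return a0 * np.exp(c * tau)
    base = a0 ** (1.0 - m) + c * (1.0 - m) * tau
    if m > 1.0 and np.any(base <= 0.0):
        raise IntegrationError(
            f"finite-time blow-up of the A**m feedback (m={m}, c={c}) within the requested window"
        )
    base = np.clip(base, 0.0, None)
    return base ** (1.0 / (1.0 - m))


def _decay(tau: np.ndarray, a0: float, k: float, order: float) -> np.ndarray:
    """Solution of dA/dt = -k * A**order from A(0) = a0 on tau >= 0."""
    tau = np.asarray(tau, dtype=float)
    if k == 0.0 or a0 == 0.0:
        return np.full_like(tau, a0)
    if abs(order - 1.0) < 1e-12:
        return a0 * np.exp(-k * tau)
    base = a0 ** (1.0 - order) + k * (order - 1.0) * tau
    if order < 1.0:
        base = np.clip(base, 0.0, None)  # extinction in finite time
    return base ** (1.0 / (1.0 - order))


def _eventless(
    times: np.ndarray, a0: float, c: float, k: float, m: float, rem_order: float
) -> np.ndarray:
    """Solution of dA/dt = c*A**m - k*A**rem_order (both terms always on)."""
    times = np.asarray(times, dtype=float)
    if k == 0.0:
        return _grow(times, a0, c, m)
    if c == 0.0:
        return _decay(times, a0, k, rem_order)
    if abs(m - rem_order) < 1e-12:
        net = c - k
        return _grow(times, a0, net, m) if net >= 0 else _decay(times, a0, -net, m)
    if abs(rem_order - 1.0) < 1e-12:
        if abs(m - 1.0) < 1e-12:
            return a0 * np.exp((c - k) * times)
        # u = A**(1-m) obeys du/dt = (1-m)(c - k u): linear ODE
        u0 = a0 ** (1.0 - m)
        ueq = c / k
        u = ueq + (u0 - ueq) * np.exp(-k * (1.0 - m) * times)
        if m > 1.0 and np.any(u <= 0.0):
            raise IntegrationError(f"finite-time blow-up of the eventless model (m={m})")
        u = np.clip(u, 0.0, None)
        return u ** (1.0 / (1.0 - m))
    # no closed form for this combination; fall back to numerics
    return _numeric_curve(times, a0, c, k, m, rem_order, event_t=None)


def _numeric_curve(
    times: np.ndarray,
    a0: float,
    c: float,
    k: float,
    m: float,
    rem_order: float,
    event_t: float | None,
) -> np.ndarray:
    """Adaptive numeric route (LSODA), split exactly at the event time."""

    def rhs_both(_t, y):
        a = max(y[0], 0.0)
        return [c * a**m - k * a**rem_order]

    def rhs_grow(_t, y):
        a = max(y[0], 0.0)
        return [c * a**m]

    def rhs_decay(_t, y):
        a = max(y[0], 0.0)
        return [-k * a**rem_order]

    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    tol = dict(rtol=1e-10, atol=1e-14)
    if event_t is None:
        sol = solve_ivp(rhs_both, (0.0, float(times[-1])), [a0], t_eval=times, method="LSODA", **tol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"numeric integration failed: {sol.message}")
        return sol.y[0]
    pre = times <= event_t
    if pre.any():
        sol = solve_ivp(rhs_grow, (0.0, event_t), [a0], t_eval=times[pre], method="LSODA", **tol)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"numeric integration failed (accumulation): {sol.message}")
        out[pre] = sol.y[0]
        a_sw = sol.y[0][-1] if times[pre][-1] == event_t else None
    else:
        a_sw = None
    if a_sw is None:
        sol = solve_ivp(rhs_grow, (0.0, event_t), [a0], method="LSODA", **tol)
        if not sol.success:
            raise IntegrationError(f"numeric integration failed (accumulation): {sol.message}")
        a_sw = sol.y[0][-1]
    post = ~pre
    if post.any():
        sol = solve_ivp(
            rhs_decay,
            (event_t, float(times[-1])),
            [a_sw],
            t_eval=times[post],
            method="LSODA",
            **tol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"numeric integration failed (removal): {sol.message}")
        out[post] = sol.y[0]
    return out


def nonselective_curve(
    times: np.ndarray,
    params: NonselectiveParams,
    variant: ModelVariant,
    wortmannin: bool = False,
    method: str = "analytic",
) -> np.ndarray:
    """Evaluate A(t) of a nonselective variant at arbitrary times >= 0.

    ``method='analytic'`` uses the exact piecewise closed-form solution;
    ``method='numeric'`` the adaptive integrator (slow, used for
    cross-validation of the analytic route).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    c = rate_accumulation(1.0, params, wortmannin, variant)  # kprod * w_acc
    k = rate_removal(1.0, params, wortmannin, variant)  # krem * w_rem
    rem_order = params.m if params.removal_order_m else 1.0
    a0 = params.atg13_seed
    if method == "numeric":
        return _numeric_curve(times, a0, c, k, params.m, rem_order, params.t if variant.event_based else None)
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    if not variant.event_based:
        return _eventless(times, a0, c, k, params.m, rem_order)
    out = np.empty_like(times)
    pre = times < params.t
    out[pre] = _grow(times[pre], a0, c, params.m)
    a_peak = float(_grow(np.array([params.t]), a0, c, params.m)[0])
    out[~pre] = _decay(times[~pre] - params.t, a_peak, k, rem_order)
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite trajectory values")
    return out


def simulate_nonselective(
    params: NonselectiveParams,
    variant: ModelVariant,
    wortmannin: bool = False,
    horizon: float = 600.0,
    dt: float = OUTPUT_DT,
    method: str = "analytic",
    condition: str | None = None,
    repeat_id: str = "sim",
) -> TimeCourse:
    """Simulate one pulse on a regular grid [0, horizon] with step dt."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if variant.event_based and horizon <= params.t:
        raise ValueError(f"horizon ({horizon}) must exceed the event time t ({params.t})")
    times = np.arange(0.0, horizon + 0.5 * dt, dt)
    a = nonselective_curve(times, params, variant, wortmannin, method=method)
    if condition is None:
        condition = "starvation+wortmannin" if wortmannin else "starvation"
    return TimeCourse(times, a, condition=condition, repeat_id=repeat_id)


# ---------------------------------------------------------------------------
# simulated kymographs
# ---------------------------------------------------------------------------


def _sample_peak_times(dist: tuple, n: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Draw n positive peak times; resample non-positive normal draws."""
    kind = dist[0]
    if kind == "normal":
        mu, sd = float(dist[1]), float(dist[2])
        if sd < 0:
            raise ValueError("sd must be >= 0")
        out = np.empty(n)
        resampled = 0
        for i in range(n):
            x = rng.normal(mu, sd)
            while x <= 0:
                resampled += 1
                x = rng.normal(mu, sd)
            out[i] = x
        return out, resampled
    if kind == "lognormal":
        meanlog, sdlog = float(dist[1]), float(dist[2])
        if sdlog < 0:
            raise ValueError("sdlog must be >= 0")
        return rng.lognormal(meanlog, sdlog, size=n), 0
    raise ValueError(f"unknown peak-time distribution {kind!r}")


def normalize_unit(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant row maps to zeros."""
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def simulate_kymograph(
    n: int,
    peak_time_dist: tuple,
    params: NonselectiveParams,
    variant: ModelVariant = ModelVariant(3),
    wortmannin: bool = False,
    seed: int = 0,
    dt: float = OUTPUT_DT,
    horizon: float | None = None,
) -> Kymograph:
    """Simulate n repeats with random event times, as a sorted kymograph.

    Each repeat runs the event-based pulse with its own sampled time to
    peak, is min-max normalized to [0, 1], and rows are stacked sorted by
    decreasing peak time (stable in repeat order on ties).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ts, n_resampled = _sample_peak_times(peak_time_dist, n, rng)
    if n_resampled:
        logger.info("resampled %d non-positive peak-time draws", n_resampled)
    if horizon is None:
        horizon = float(np.ceil((ts.max() * 1.3 + 200.0) / dt) * dt)
    times = np.arange(0.0, horizon + 0.5 * dt, dt)
    rows = np.empty((n, times.size))
    peak_times = np.empty(n)
    for i, t_i in enumerate(ts):
        a = nonselective_curve(times, params.replace(t=float(t_i)), variant, wortmannin)
        rows[i] = normalize_unit(a)
        peak_times[i] = times[int(np.argmax(a))]
    order = np.argsort(-peak_times, kind="stable")
    return Kymograph(
        matrix=rows[order],
        row_order=[str(i) for i in order],
        times=times,
        peak_times=peak_times[order],
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# hybrid stochastic mitophagy model
# ---------------------------------------------------------------------------


def delay_for_cycle(k: int | np.ndarray, kpeak: float, p: float) -> float | np.ndarray:
    """Inter-aggregation delay after completed cycle k: kpeak * k**p, s."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 1):
        raise ValueError("cycle index k must be >= 1")
    out = kpeak * k_arr**p
    return float(out) if np.isscalar(k) or out.ndim == 0 else out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One Normal(mean, sd) draw, resampled until > 0."""
    if sd == 0.0:
        if mean <= 0:
            raise ValueError("degenerate truncated normal with non-positive mean")
        return mean
    x = rng.normal(mean, sd)
    while x <= 0:
        x = rng.normal(mean, sd)
    return x


@dataclass
class MitophagySimResult:
    """One simulated mitophagy event.

    ``trace`` is the observable ATG13 signal on the imaging grid, ``lc3``
    the cumulative LC3 prediction, ``peak_num`` the step series of
    completed aggregation cycles aligned to ``trace.times``.
    """

    trace: TimeCourse
    lc3: TimeCourse
    peak_num: np.ndarray
    peak_times: np.ndarray  # s, time of each aggregation peak
    peak_delay_obs: np.ndarray  # s, programmed delay after each cycle
    sampled_t: np.ndarray  # s, per-cycle time-to-peak draws
    mt_diam: float  # um
    termination_time: float  # s
    lc3_per_cycle: np.ndarray = field(default_factory=lambda: np.empty(0))
    completed: bool = True  # False only when a max_time cutoff stopped the run

    def n_peaks(self, by_time: float | None = None) -> int:
        """Completed aggregation peaks, optionally up to a checkpoint."""
        if by_time is None:
            return int(self.peak_times.size)
        return int(np.searchsorted(self.peak_times, by_time, side="right"))


_BASELINE_FACTOR = 1.05  # cycle ends when A < 1.05 * atg13_seed
_MAX_CYCLES = 1000


def simulate_mitophagy(
    params: MitophagyParams,
    seed: int | np.random.Generator = 0,
    dt: float = OUTPUT_DT,
    fine_dt: float = 1.0,
    max_time: float | None = None,
) -> MitophagySimResult:
    """Run one hybrid mitophagy event until engulfment completes.

    Cycle k: ATG13 accumulates for a sampled time-to-peak t_k, then is
    removed until it returns near baseline; cumulative LC3 grows at
    kprodLC3 * A while the cycle runs. After a delay kpeak * k**p the
    model checks (with lag Tau) whether cumulative LC3 has reached
    engulf_coeff * mt_diam; if so the event terminates, otherwise the
    next aggregation starts.

    ``max_time`` optionally cuts the run off (``completed=False``); used
    when only a fixed observation window matters, e.g. inside objective
    functions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mt_diam = _truncated_normal(rng, params.mt_diam_mean, params.mt_diam_sd)
    threshold = params.engulf_coeff * mt_diam
    if params.kprodLC3 == 0.0 and threshold > 0.0:
        raise EngulfmentError("engulfment cannot complete: kprodLC3 = 0 with a positive threshold")
    if params.kremATG13 == 0.0:
        raise EngulfmentError("engulfment cannot complete: kremATG13 = 0, ATG13 never returns to baseline")

    a0 = params.atg13_seed
    baseline = _BASELINE_FACTOR * a0
    seg_times: list[np.ndarray] = [np.array([0.0])]
    seg_a: list[np.ndarray] = [np.array([a0])]
    seg_lc3: list[np.ndarray] = [np.array([0.0])]

    t_abs = 0.0
    lc3_total = 0.0
    peak_times: list[float] = []
    sampled_t: list[float] = []
    delays: list[float] = []
    lc3_per_cycle: list[float] = []
    termination_time = np.nan
    completed = True

    for k in range(1, _MAX_CYCLES + 1):
        t_k = _truncated_normal(rng, params.t_mean, params.t_sd)
        pulse = params.pulse_params(t=t_k)
        c = pulse.kprodATG13
        a_peak = float(_grow(np.array([t_k]), a0, c, params.m)[0])
        rem_order = params.m if params.removal_order_m else 1.0
        if a_peak <= baseline:
            tau_rem = 0.0
        elif abs(rem_order - 1.0) < 1e-12:
            tau_rem = float(np.log(a_peak / baseline) / params.kremATG13)
        else:  # solve a_peak-decay crossing of the baseline for general order
            tau_rem = float(
                (baseline ** (1.0 - rem_order) - a_peak ** (1.0 - rem_order))
                / (params.kremATG13 * (rem_order - 1.0))
            )
        dur = t_k + tau_rem
        n_pts = max(int(np.ceil(dur / fine_dt)), 2)
        local = np.linspace(0.0, dur, n_pts + 1)[1:]
        a_local = np.where(
            local < t_k,
            _grow(local, a0, c, params.m),
            _decay(np.clip(local - t_k, 0.0, None), a_peak, params.kremATG13, rem_order),
        )
        # cumulative LC3 via trapezoid on the fine grid, continuing from lc3_total
        prev_t = seg_times[-1][-1]
        prev_a = seg_a[-1][-1]
        all_t = np.concatenate(([prev_t], t_abs + local))
        all_a = np.concatenate(([prev_a], a_local))
        incr = np.cumsum(
            0.5 * (all_a[1:] + all_a[:-1]) * np.diff(all_t) * params.kprodLC3
        )
        seg_times.append(t_abs + local)
        seg_a.append(a_local)
        seg_lc3.append(lc3_total + incr)
        lc3_per_cycle.append(float(incr[-1]))
        lc3_total += float(incr[-1])
        peak_times.append(t_abs + t_k)
        sampled_t.append(t_k)
        t_end = t_abs + dur

        delay_k = float(delay_for_cycle(k, params.kpeak, params.p))
        delays.append(delay_k)
        t_eval = t_end + delay_k
        # the inter-cycle gap is constant (A at seed, LC3 flat), so two
        # boundary points represent it exactly under linear interpolation
        if delay_k > 0:
            gap = np.array([t_end + min(fine_dt, delay_k) * 1e-3, t_eval])
            seg_times.append(gap)
            seg_a.append(np.full(gap.size, a0))
            seg_lc3.append(np.full(gap.size, lc3_total))
        # threshold check at t_eval, reading LC3 at (t_eval - Tau)
        t_read = max(t_eval - params.Tau, 0.0)
        lc3_at_read = float(
            np.interp(t_read, np.concatenate(seg_times), np.concatenate(seg_lc3))
        )
        if lc3_at_read >= threshold:
            termination_time = t_eval
            break
        if max_time is not None and t_eval > max_time:
            termination_time = t_eval
            completed = False
            break
        t_abs = t_eval
    else:
        raise EngulfmentError(
            f"engulfment did not complete within {_MAX_CYCLES} cycles "
            f"(threshold {threshold:.3g}, cumulative LC3 {lc3_total:.3g})"
        )

    t_fine = np.concatenate(seg_times)
    a_fine = np.concatenate(seg_a)
    lc3_fine = np.concatenate(seg_lc3)
    grid = np.arange(0.0, termination_time + 0.5 * dt, dt)
    if grid.size < 3:
        grid = np.arange(0.0, 3 * dt, dt)
    a_grid = np.interp(grid, t_fine, a_fine)
    lc3_grid = np.interp(grid, t_fine, lc3_fine)
    pt = np.asarray(peak_times)
    peak_num = np.searchsorted(pt, grid, side="right").astype(int)
    return MitophagySimResult(
        trace=TimeCourse(grid, a_grid, condition="ivermectin", repeat_id="sim"),
        lc3=TimeCourse(grid, lc3_grid, condition="ivermectin", repeat_id="sim-lc3"),
        peak_num=peak_num,
        peak_times=pt,
        peak_delay_obs=np.asarray(delays),
        sampled_t=np.asarray(sampled_t),
        mt_diam=mt_diam,
        termination_time=float(termination_time),
        lc3_per_cycle=np.asarray(lc3_per_cycle),
        completed=completed,
    )


def simulate_mitophagy_population(
    n: int,
    params: MitophagyParams,
    seed: int = 0,
    dt: float = OUTPUT_DT,
    fine_dt: float = 1.0,
) -> list[MitophagySimResult]:
    """Simulate n independent mitophagy events.

    Each event draws its own mitochondrial diameter and per-cycle
    times-to-peak from the truncated normal distributions in ``params``.
    """
    if n < 2:
        raise ValueError("a population needs n >= 2 events")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        res = simulate_mitophagy(params, np.random.default_rng(child), dt=dt, fine_dt=fine_dt)
        res.trace.repeat_id = str(i)
        res.lc3.repeat_id = f"{i}-lc3"
        out.append(res)
    return out
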