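"""Synthetic datasets with the statistical structure of the imaging study.

The raw movies behind the analysis are not publicly deposited, so these
generators stand in for them: single-peak nonselective pulses with peak
times drawn Normal (starvation) or LogNormal (starvation plus
wortmannin, with reduced amplitude), and oscillatory mitophagy events
from the hybrid stochastic model, both degraded by multiplicative
lognormal noise and a slow exponential photobleaching-like decline.
Every bundle records its generating truth for recovery tests.

Kinetic defaults are the published fits; distribution, noise and bleach
settings are not published and are package choices (documented in the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MitophagyParams, ModelVariant, NonselectiveParams
from .simulate import TimeCourse, nonselective_curve, simulate_mitophagy_population

__all__ = [
    "NoiseConfig",
    "GroundTruthBundle",
    "DEFAULT_PEAK_TIME_DISTS",
    "gen_nonselective_population",
    "gen_mitophagy_population",
    "gen_diameters",
]

# peak-time distributions per condition (not published; wortmannin gets a
# clearly right-skewed log-normal and a reduced-amplitude pulse)
DEFAULT_PEAK_TIME_DISTS = {
    "starvation": ("normal", 200.0, 40.0),
    "starvation+wortmannin": ("lognormal", float(np.log(120.0)), 0.8),
}


@dataclass
class NoiseConfig:
    """Measurement degradation: multiplicative lognormal noise with the
    given sd fraction, and an exponential signal decline with time
    constant ``bleach_tau`` (None disables bleaching)."""

    multiplicative_sd: float = 0.05
    bleach_tau: float | None = 600.0

    def apply(self, times: np.ndarray, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = values.copy()
        if self.multiplicative_sd > 0:
            sd = self.multiplicative_sd
            # lognormal factors with unit mean
            out = out * rng.lognormal(-0.5 * sd**2, sd, size=out.shape)
        if self.bleach_tau is not None:
            out = out * np.exp(-(times - times[0]) / self.bleach_tau)
        return out


@dataclass
class GroundTruthBundle:
    """Synthetic traces plus every generating truth needed for recovery."""

    traces: list[TimeCourse]
    generating_params: NonselectiveParams | MitophagyParams
    true_peak_times: np.ndarray
    true_peak_counts: np.ndarray
    true_diameters: np.ndarray
    noise_cfg: NoiseConfig
    seed: int
    irregular_ids: list[str] = field(default_factory=list)
    true_delays: list[np.ndarray] = field(default_factory=list)
    sim_results: list = field(default_factory=list)


def _sample_positive(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "normal":
        x = rng.normal(dist[1], dist[2])
        while x <= 0:
            x = rng.normal(dist[1], dist[2])
        return float(x)
    if kind == "lognormal":
        return float(rng.lognormal(dist[1], dist[2]))
    raise ValueError(f"unknown peak-time distribution {kind!r}")


def gen_nonselective_population(
    n: int,
    condition: str = "starvation",
    peak_time_dist: tuple | None = None,
    params: NonselectiveParams | None = None,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    variant: ModelVariant = ModelVariant(3),
    dt: float = 10.0,
) -> GroundTruthBundle:
    """Generate n single-pulse traces for one condition.

    Each repeat simulates the event-based pulse with an independently
    sampled time-to-peak; a condition containing "wortmannin" activates
    the wortmannin factor (reduced amplitude) and defaults to LogNormal
    peak times, plain starvation to Normal ones.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or NonselectiveParams()
    noise_cfg = noise_cfg or NoiseConfig()
    wtm = "wortmannin" in condition.lower()
    if peak_time_dist is None:
        key = "starvation+wortmannin" if wtm else "starvation"
        peak_time_dist = DEFAULT_PEAK_TIME_DISTS[key]
    rng = np.random.default_rng(seed)
    ts = np.array([_sample_positive(peak_time_dist, rng) for _ in range(n)])
    horizon = float(np.ceil((ts.max() * 1.3 + 200.0) / dt) * dt)
    times = np.arange(0.0, horizon + 0.5 * dt, dt)
    traces = []
    for i, t_i in enumerate(ts):
        a = nonselective_curve(times, params.replace(t=float(t_i)), variant, wortmannin=wtm)
        y = noise_cfg.apply(times, a, rng)
        traces.append(TimeCourse(times, y, condition=condition, repeat_id=str(i)))
    return GroundTruthBundle(
        traces=traces,
        generating_params=params,
        true_peak_times=ts,
        true_peak_counts=np.ones(n, dtype=int),
        true_diameters=np.empty(0),
        noise_cfg=noise_cfg,
        seed=seed,
    )


def _irregular_trace(
    times: np.ndarray, amplitude: float, rng: np.random.Generator, repeat_id: str
) -> TimeCourse:
    """A drifting, non-oscillatory trace that fails the peak criterion."""
    drift = np.linspace(0.2 * amplitude, amplitude, times.size)
    y = drift * rng.lognormal(-0.0005, 0.03, size=times.size)
    return TimeCourse(times, y, condition="ivermectin", repeat_id=repeat_id)


def gen_mitophagy_population(
    n: int,
    params: MitophagyParams | None = None,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    n_irregular: int = 0,
    dt: float = 10.0,
) -> GroundTruthBundle:
    """Generate n oscillatory mitophagy events (plus optional irregulars).

    Wraps the hybrid stochastic simulator, then applies noise and
    bleaching. ``n_irregular`` extra drifting traces exercise the
    irregularity filter; their ids are recorded in ``irregular_ids``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or MitophagyParams()
    noise_cfg = noise_cfg or NoiseConfig()
    results = simulate_mitophagy_population(max(n, 2), params, seed=seed, dt=dt)[:n]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))  # noise stream, distinct from the simulator's
    traces = []
    amp = 0.0
    for i, res in enumerate(results):
        y = noise_cfg.apply(res.trace.times, res.trace.intensities, rng)
        traces.append(TimeCourse(res.trace.times, y, condition="ivermectin", repeat_id=str(i)))
        amp = max(amp, float(res.trace.intensities.max()))
    irregular_ids = []
    if n_irregular:
        horizon = float(np.median([tc.times[-1] for tc in traces]))
        times = np.arange(0.0, horizon + 0.5 * dt, dt)
        for j in range(n_irregular):
            rid = f"irr{j}"
            traces.append(_irregular_trace(times, amp, rng, rid))
            irregular_ids.append(rid)
    return GroundTruthBundle(
        traces=traces,
        generating_params=params,
        true_peak_times=np.array([r.peak_times[0] for r in results]),
        true_peak_counts=np.array([r.n_peaks() for r in results]),
        true_diameters=np.array([r.mt_diam for r in results]),
        noise_cfg=noise_cfg,
        seed=seed,
        irregular_ids=irregular_ids,
        true_delays=[r.peak_delay_obs for r in results],
        sim_results=results,
    )


def gen_diameters(
    n: int,
    mean_um: float = 1.0,
    sd_um: float = 0.3,
    per_event_measurements: int = 8,
    measurement_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a diameter measurements table (event_id, measurement_um).

    Per-event true diameters are truncated-Normal(mean_um, sd_um) > 0;
    each event gets ``per_event_measurements`` jittered measurements.
    Returns (table, true per-event diameters).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_um <= 0:
        raise ValueError("mean_um must be > 0")
    if sd_um < 0 or measurement_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    true = np.empty(n)
    for i in range(n):
        x = rng.normal(mean_um, sd_um) if sd_um > 0 else mean_um
        while x <= 0:
            x = rng.normal(mean_um, sd_um)
        true[i] = x
    rows = []
    for i, d in enumerate(true):
        meas = d + rng.normal(0.0, measurement_sd, size=per_event_measurements)
        meas = np.abs(meas)  # measurement jitter cannot go negative
        rows.append(pd.DataFrame({"event_id": f"ev{i}", "measurement_um": meas}))
    return pd.concat(rows, ignore_index=True), true
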