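"""Rate laws and parameter sets for ATG13 punctum kinetics.

The nonselective-autophagy model describes a single ATG13 punctum as one
state variable ``A`` (aggregated ATG13, arbitrary fluorescence units) with

    dA/dt = accumulation - removal
    accumulation = kprodATG13 * A**m        (cooperative self-aggregation)
    removal      = kremATG13  * A           (first-order dissociation)

Six variants differ in (a) whether a discrete event at time ``t`` switches
the system from pure accumulation to pure removal (variants 1-3) or both
reactions run simultaneously (variants 4-6), and (b) which reaction the
PI3K inhibitor wortmannin down-regulates by the factor ``kwrtm``:
accumulation (1, 4), removal (2, 5) or both (3, 6).

The mitophagy model extends this with cumulative LC3 production driven by
aggregated ATG13, repeated aggregation cycles separated by power-law
growing delays, and diameter-dependent termination of engulfment; its
parameter set lives here, the hybrid simulation in :mod:`atgdyn.simulate`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal

__all__ = [
    "WortmanninTarget",
    "ModelVariant",
    "NonselectiveParams",
    "MitophagyParams",
    "rate_accumulation",
    "rate_removal",
]

WortmanninTarget = Literal["accumulation", "removal", "both"]

_TARGET_BY_MOD = {1: "accumulation", 2: "removal", 0: "both"}


@dataclass(frozen=True)
class ModelVariant:
    """One of the six nonselective model configurations.

    Variants 1-3 are event-based (a hard switch from accumulation to
    removal at time ``t``); variants 4-6 are eventless. The wortmannin
    target cycles accumulation/removal/both as variant_id mod 3 = 1/2/0.
    """

    variant_id: int

    def __post_init__(self) -> None:
        if self.variant_id not in range(1, 7):
            raise ValueError(f"variant_id must be in 1..6, got {self.variant_id}")

    @property
    def event_based(self) -> bool:
        return self.variant_id <= 3

    @property
    def wortmannin_target(self) -> WortmanninTarget:
        return _TARGET_BY_MOD[self.variant_id % 3]  # type: ignore[return-value]

    @property
    def targets_accumulation(self) -> bool:
        return self.wortmannin_target in ("accumulation", "both")

    @property
    def targets_removal(self) -> bool:
        return self.wortmannin_target in ("removal", "both")

    def to_json(self) -> str:
        return json.dumps({"variant_id": self.variant_id})

    @classmethod
    def from_json(cls, s: str) -> "ModelVariant":
        return cls(json.loads(s)["variant_id"])


@dataclass
class NonselectiveParams:
    """Parameters of the single-pulse ATG13 model.

    kprodATG13 : accumulation rate constant, AU^(1-m) s^-1
    kremATG13  : removal rate constant, s^-1
    m          : partial reaction order of aggregated ATG13 in accumulation
    kwrtm      : wortmannin down-regulation factor in (0, 1]
    t          : event time from initiation to the accumulation->removal
                 switch, s (used by variants 1-3 only)
    atg13_seed : initial aggregated ATG13, AU; must be > 0 because the
                 A**m feedback stalls at exactly zero
    removal_order_m : if True the removal reaction carries the same partial
                 order m instead of being first order (alternative reading
                 of the cooperativity hypothesis)
    """

    kprodATG13: float = 0.0082
    kremATG13: float = 0.0029
    m: float = 1.01365
    kwrtm: float = 0.5
    t: float = 200.0
    atg13_seed: float = 0.01
    removal_order_m: bool = False

    def __post_init__(self) -> None:
        if self.kprodATG13 < 0 or self.kremATG13 < 0:
            raise ValueError("rate constants must be >= 0")
        if not (0.0 < self.kwrtm <= 1.0):
            raise ValueError(f"kwrtm must be in (0, 1], got {self.kwrtm}")
        if self.t <= 0:
            raise ValueError("event time t must be > 0")
        if self.atg13_seed <= 0:
            raise ValueError("atg13_seed must be > 0")
        if self.m < 0:
            raise ValueError("partial order m must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NonselectiveParams":
        return cls(**json.loads(s))

    def replace(self, **kw) -> "NonselectiveParams":
        d = asdict(self)
        d.update(kw)
        return NonselectiveParams(**d)


@dataclass
class MitophagyParams:
    """Parameters of the hybrid stochastic mitophagy model.

    Extends the nonselective kinetics with LC3-mediated engulfment:

    kprodLC3     : LC3 production rate per unit aggregated ATG13, s^-1
    kpeak        : base inter-aggregation delay coefficient, s
    p            : delay growth exponent (delay after cycle k = kpeak*k**p)
    Tau          : lag before LC3 inhibits a new ATG13 accumulation, s
    t_mean, t_sd : Normal distribution of per-cycle time-to-peak, s
    mt_diam_mean, mt_diam_sd : Normal distribution of mitochondrial
                   fragment diameters, um (truncated > 0 when sampled)
    engulf_coeff : cumulative LC3 required per um of diameter for full
                   engulfment, AU um^-1

    Kinetic-rate defaults are the fitted mitophagy values; distribution and
    engulfment defaults are not published and were chosen to reproduce the
    qualitative study conditions (~5-6 aggregation cycles at the mean
    diameter within ~900 s).
    """

    kprodATG13: float = 0.0114
    kremATG13: float = 0.0114
    m: float = 1.01365
    kprodLC3: float = 0.1
    kpeak: float = 0.7
    p: float = 2.79
    Tau: float = 0.0
    t_mean: float = 45.0
    t_sd: float = 9.0
    mt_diam_mean: float = 1.0
    mt_diam_sd: float = 0.3
    engulf_coeff: float = 0.65
    atg13_seed: float = 0.01
    removal_order_m: bool = False

    def __post_init__(self) -> None:
        for name in ("kprodATG13", "kremATG13", "kprodLC3", "kpeak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.t_sd < 0 or self.mt_diam_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.engulf_coeff <= 0:
            raise ValueError("engulf_coeff must be > 0")
        if self.Tau < 0:
            raise ValueError("Tau must be >= 0")
        if self.m < 0:
            raise ValueError("partial order m must be >= 0")
        if self.atg13_seed <= 0:
            raise ValueError("atg13_seed must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MitophagyParams":
        return cls(**json.loads(s))

    def replace(self, **kw) -> "MitophagyParams":
        d = asdict(self)
        d.update(kw)
        return MitophagyParams(**d)

    def pulse_params(self, t: float) -> NonselectiveParams:
        """Nonselective parameter view of one aggregation cycle."""
        return NonselectiveParams(
            kprodATG13=self.kprodATG13,
            kremATG13=self.kremATG13,
            m=self.m,
            kwrtm=1.0,
            t=t,
            atg13_seed=self.atg13_seed,
            removal_order_m=self.removal_order_m,
        )


def _wortmannin_factor(active: bool, kwrtm: float, targeted: bool) -> float:
    return kwrtm if (active and targeted) else 1.0


def rate_accumulation(
    A: float,
    params: NonselectiveParams,
    wortmannin_active: bool = False,
    variant: ModelVariant = ModelVariant(3),
) -> float:
    """ATG13 accumulation rate kprodATG13 * A**m, AU s^-1.

    The partial order ``m`` encodes cooperativity of aggregation on the
    already aggregated complex; wortmannin multiplies the rate by
    ``kwrtm`` when the variant targets accumulation (or both).
    """
    if A < 0:
        raise ValueError(f"aggregated ATG13 must be >= 0, got {A}")
    w = _wortmannin_factor(wortmannin_active, params.kwrtm, variant.targets_accumulation)
    if A == 0.0:
        return 0.0 if params.m > 0 else params.kprodATG13 * w
    return params.kprodATG13 * A**params.m * w


def rate_removal(
    A: float,
    params: NonselectiveParams,
    wortmannin_active: bool = False,
    variant: ModelVariant = ModelVariant(3),
) -> float:
    """ATG13 removal rate kremATG13 * A (first order by default), AU s^-1.

    With ``params.removal_order_m`` the removal carries the partial order m
    as well, the alternative reading in which cooperativity speeds both
    directions of the aggregation equilibrium.
    """
    if A < 0:
        raise ValueError(f"aggregated ATG13 must be >= 0, got {A}")
    w = _wortmannin_factor(wortmannin_active, params.kwrtm, variant.targets_removal)
    order = params.m if params.removal_order_m else 1.0
    if A == 0.0:
        return 0.0 if order > 0 else params.kremATG13 * w
    return params.kremATG13 * A**order * w
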