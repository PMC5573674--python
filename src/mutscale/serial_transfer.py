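"""Daily serial-transfer (dilution-and-regrowth) evolution simulator.

Each day the culture is split across eight wells at dilutions 10^1..10^8
into fresh medium, incubated, and the single well found in early exponential
phase (OD600 inside a selection window, default 0.001-0.05) is carried to
the next day. Generations accumulate as log2 of the daily regrowth factor:

    generations_today = log2(od_selected * dilution / od_previous)

The default deterministic regrowth is calibrated to 8 generations/day
(mu = 8 ln2 / incubation_h), so the full 50-day protocol accumulates 400
generations. Growth-rate adaptation is optional: mu rises with cumulative
generations following a saturating (hyperbolic) curve, and the mutation
rate is tied to mu through the growth-rate coupling law
log10(M) = log10(M0) + alpha * mu, so every trajectory point lies exactly
on that line by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransferProtocol",
    "AdaptationModel",
    "TransferState",
    "Trajectory",
    "ProtocolFailureError",
    "DEFAULT_MU_PER_DAY",
    "constant_model",
    "no28_adaptation",
    "select_well",
    "simulate_transfer_day",
    "run_serial_transfer",
]

# growth rate giving exactly 8 doublings per 24 h incubation
DEFAULT_MU_PER_DAY = 8.0 * math.log(2.0) / 24.0  # ~0.2310 h^-1


class ProtocolFailureError(RuntimeError):
    """No well in the selection window (washout or saturation)."""


@dataclass(frozen=True)
class TransferProtocol:
    n_days: int = 50
    dilution_ratios: tuple[float, ...] = tuple(10.0**k for k in range(1, 9))
    od_window: tuple[float, float] = (0.001, 0.05)
    incubation_h: float = 24.0
    tie_break: str = "geometric_midpoint"
    carrying_capacity: float = 1.0

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.dilution_ratios, self.dilution_ratios[1:])
        ):
            raise ValueError("dilution_ratios must be strictly increasing")
        if not self.od_window[0] < self.od_window[1]:
            raise ValueError("od_window lower bound must be below upper bound")
        if self.n_days < 0 or self.incubation_h <= 0:
            raise ValueError("n_days must be >= 0 and incubation_h positive")


@dataclass(frozen=True)
class AdaptationModel:
    """Saturating growth-rate gain with the mutation-rate coupling law.

    mu(g) = mu_start + (mu_max - mu_start) * g / (g + half_saturation_generations)
    M(mu) = 10**(log10_M0 + alpha * mu)
    """

    mu_start: float = DEFAULT_MU_PER_DAY
    mu_max: float = DEFAULT_MU_PER_DAY
    half_saturation_generations: float = 100.0
    alpha: float = -4.9  # M63 coupling slope
    log10_M0: float = -6.1

    def __post_init__(self) -> None:
        if self.mu_start > self.mu_max:
            raise ValueError("mu_start must not exceed mu_max")
        if self.half_saturation_generations <= 0:
            raise ValueError("half_saturation_generations must be positive")

    def mu_at(self, generations: float) -> float:
        gain = self.mu_max - self.mu_start
        g = generations
        return self.mu_start + gain * g / (g + self.half_saturation_generations)

    def rate_at(self, mu: float) -> float:
        return 10.0 ** (self.log10_M0 + self.alpha * mu)


def constant_model(mu: float = DEFAULT_MU_PER_DAY, **kw) -> AdaptationModel:
    """Adaptation disabled: growth rate fixed at ``mu``."""
    return AdaptationModel(mu_start=mu, mu_max=mu, **kw)


def no28_adaptation(
    mu_start: float = DEFAULT_MU_PER_DAY,
    fold_gain_at_400: float = 1.3,
    half_saturation_generations: float = 100.0,
    **kw,
) -> AdaptationModel:
    """Preset emulating the evolved reduced genome: mu rises ``fold_gain_at_400``
    fold over 400 generations of transfer."""
    frac = 400.0 / (400.0 + half_saturation_generations)
    mu_max = mu_start * (1.0 + (fold_gain_at_400 - 1.0) / frac)
    return AdaptationModel(
        mu_start=mu_start,
        mu_max=mu_max,
        half_saturation_generations=half_saturation_generations,
        **kw,
    )


@dataclass(frozen=True)
class TransferState:
    day: int
    od_at_selection: float
    selected_dilution: float
    generations_today: float
    cumulative_generations: float
    mu_current: float
    M_current: float


def select_well(
    well_ods: np.ndarray, protocol: TransferProtocol
) -> tuple[int, float]:
    """Index and OD of the well inside the selection window.

    Ties (several wells in window) are broken by proximity to the geometric
    midpoint sqrt(lo*hi) of the window, measured on the log scale.
    """
    lo, hi = protocol.od_window
    ods = np.asarray(well_ods, dtype=float)
    candidates = np.flatnonzero((ods >= lo) & (ods <= hi))
    if candidates.size == 0:
        raise ProtocolFailureError(
            "protocol failure (washout or saturation): no well with OD in "
            f"[{lo}, {hi}]"
        )
    if candidates.size == 1:
        i = int(candidates[0])
        return i, float(ods[i])
    if protocol.tie_break != "geometric_midpoint":
        raise ValueError(f"unknown tie_break rule {protocol.tie_break!r}")
    midpoint = math.sqrt(lo * hi)
    dist = np.abs(np.log(ods[candidates]) - math.log(midpoint))
    i = int(candidates[np.argmin(dist)])
    return i, float(ods[i])


def _overnight_ods(
    od_previous: float,
    mu: float,
    protocol: TransferProtocol,
    rng: np.random.Generator | None,
    od_noise_sd: float,
) -> np.ndarray:
    dilutions = np.asarray(protocol.dilution_ratios)
    start = od_previous / dilutions
    grown = start * math.exp(mu * protocol.incubation_h)
    if od_noise_sd > 0:
        if rng is None:
            raise ValueError("stochastic OD noise requires a seeded generator")
        grown = grown * np.exp(rng.normal(0.0, od_noise_sd, size=grown.shape))
    return np.minimum(grown, protocol.carrying_capacity)


def simulate_transfer_day(
    state: TransferState,
    protocol: TransferProtocol,
    model: AdaptationModel,
    rng: np.random.Generator | None = None,
    od_noise_sd: float = 0.0,
) -> TransferState:
    """Advance one day: regrow all dilution wells, select, account generations."""
    mu = model.mu_at(state.cumulative_generations)
    ods = _overnight_ods(state.od_at_selection, mu, protocol, rng, od_noise_sd)
    try:
        idx, od_sel = select_well(ods, protocol)
    except ProtocolFailureError as err:
        raise ProtocolFailureError(f"day {state.day + 1}: {err}") from None
    dilution = protocol.dilution_ratios[idx]
    gens = math.log2(od_sel * dilution / state.od_at_selection)
    return TransferState(
        day=state.day + 1,
        od_at_selection=od_sel,
        selected_dilution=dilution,
        generations_today=gens,
        cumulative_generations=state.cumulative_generations + gens,
        mu_current=mu,
        M_current=model.rate_at(mu),
    )


@dataclass(frozen=True)
class Trajectory:
    states: tuple[TransferState, ...]

    @property
    def cumulative_generations(self) -> float:
        return self.states[-1].cumulative_generations if self.states else 0.0

    @property
    def mu_fold_change(self) -> float:
        if not self.states:
            return 1.0
        return self.states[-1].mu_current / self.states[0].mu_current

    @property
    def delta_log10_M(self) -> float:
        if not self.states:
            return 0.0
        return math.log10(self.states[-1].M_current) - math.log10(
            self.states[0].M_current
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [s.day for s in self.states],
                "selected_dilution": [s.selected_dilution for s in self.states],
                "od": [s.od_at_selection for s in self.states],
                "generations_today": [s.generations_today for s in self.states],
                "cumulative_generations": [
                    s.cumulative_generations for s in self.states
                ],
                "mu": [s.mu_current for s in self.states],
                "M": [s.M_current for s in self.states],
            }
        )


def run_serial_transfer(
    protocol: TransferProtocol = TransferProtocol(),
    model: AdaptationModel | None = None,
    seed: int | None = None,
    od_noise_sd: float = 0.0,
    od_start: float = 0.01,
) -> Trajectory:
    """Run the full serial-transfer protocol and return the daily trajectory.

    With ``model=None`` adaptation is disabled (constant default growth
    rate, 8 generations/day). OD noise, when enabled, is multiplicative
    log-normal and seeded.
    """
    if model is None:
        model = constant_model()
    rng = np.random.default_rng(seed) if seed is not None else None
    state = TransferState(
        day=0,
        od_at_selection=od_start,
        selected_dilution=math.nan,
        generations_today=0.0,
        cumulative_generations=0.0,
        mu_current=model.mu_at(0.0),
        M_current=model.rate_at(model.mu_at(0.0)),
    )
    states: list[TransferState] = []
    for _ in range(protocol.n_days):
        state = simulate_transfer_day(
            state, protocol, model, rng=rng, od_noise_sd=od_noise_sd
        )
        states.append(state)
    return Trajectory(states=tuple(states))
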