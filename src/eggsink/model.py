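"""Update rules and simulation of the discrete-time egg-sink model.

One generation maps ``(H1, H2, P)`` to

    H_i' = H_i * g(H_i) * (1 - (s_i + mu_i) * (1 - f(eps_i)))
    P'   = X * (s1*H1*(1 - f(eps_1)) + s2*H2*(1 - f(eps_2)))

with Ricker growth ``g(H) = exp(r (1 - H/K))``, negative-binomial escape
``f(eps) = (1 + eps/k)^(-k)`` and a saturating, egg-limited encounter
rate ``eps_i = a_i * beta * P / (beta + a1*H1 + a2*H2)``.  The shared
denominator is the egg-sink mechanism: hosts of either species absorb
parasitoid eggs, so adding unsuitable hosts lowers the encounter rate
experienced by suitable hosts.

All quantities for a generation are evaluated synchronously from the
pre-step state.  Abundances are continuous; extinction (H_i = 0) is
absorbing by the multiplicative form, and no artificial floor is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import InvalidParameterError, ModelParams, PopulationState

__all__ = [
    "ricker_growth",
    "encounter_rate",
    "encounter_rates",
    "escape_fraction",
    "step",
    "simulate",
    "Trajectory",
]


def ricker_growth(H, r: float, K: float):
    """Ricker growth multiplier ``g = exp(r * (1 - H/K))``.

    Accepts scalar or array ``H``; strictly decreasing in ``H`` for
    ``r > 0`` and equal to 1 at ``H = K``.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)) or np.any(H < 0):
        raise InvalidParameterError(f"H must be finite and >= 0, got {H!r}")
    if not (math.isfinite(K) and K > 0):
        raise InvalidParameterError(f"K must be > 0, got {K!r}")
    if not math.isfinite(r):
        raise InvalidParameterError(f"r must be finite, got {r!r}")
    out = np.exp(r * (1.0 - H / K))
    return float(out) if out.ndim == 0 else out


def encounter_rates(state: PopulationState, params: ModelParams) -> tuple[float, float]:
    """Expected parasitoid encounters per host, ``eps_i``, for both hosts.

    eps_i = a_i * beta * P / (beta + a1*H1 + a2*H2).  The denominator
    pools egg demand over both host species, so eps_1 decreases when
    unsuitable hosts are added (the egg sink) and eps_i is bounded above
    by ``a_i * P`` (the denominator is at least beta).
    """
    st = PopulationState(*state).validate()
    a1, a2 = params.host1.a, params.host2.a
    beta = params.parasitoid.beta
    denom = beta + a1 * st.H1 + a2 * st.H2
    common = beta * st.P / denom
    return a1 * common, a2 * common


def encounter_rate(state: PopulationState, params: ModelParams, host_index: int) -> float:
    """``eps`` for a single host species (``host_index`` 1 or 2)."""
    e1, e2 = encounter_rates(state, params)
    if host_index == 1:
        return e1
    if host_index == 2:
        return e2
    raise InvalidParameterError(f"host_index must be 1 or 2, got {host_index!r}")


def escape_fraction(epsilon, k_agg: float):
    """Proportion of hosts escaping parasitism, ``f = (1 + eps/k)^(-k)``.

    The zero-encounter term of a negative-binomial attack distribution
    with aggregation ``k_agg``; tends to the Poisson ``exp(-eps)`` as
    ``k_agg`` grows.
    """
    eps = np.asarray(epsilon, dtype=float)
    if not np.all(np.isfinite(eps)) or np.any(eps < 0):
        raise InvalidParameterError(f"epsilon must be finite and >= 0, got {epsilon!r}")
    if not (math.isfinite(k_agg) and k_agg > 0):
        raise InvalidParameterError(f"k_agg must be > 0, got {k_agg!r}")
    out = np.power(1.0 + eps / k_agg, -k_agg)
    return float(out) if out.ndim == 0 else out


def step(state: PopulationState, params: ModelParams) -> PopulationState:
    """Advance the system by one generation (synchronous update)."""
    st = PopulationState(*state).validate()
    h1, h2, par = params.host1, params.host2, params.parasitoid
    e1, e2 = encounter_rates(st, params)
    f1 = escape_fraction(e1, par.k_agg)
    f2 = escape_fraction(e2, par.k_agg)
    g1 = ricker_growth(st.H1, h1.r, h1.K)
    g2 = ricker_growth(st.H2, h2.r, h2.K)
    H1n = st.H1 * g1 * (1.0 - (h1.s + h1.mu) * (1.0 - f1))
    H2n = st.H2 * g2 * (1.0 - (h2.s + h2.mu) * (1.0 - f2))
    Pn = par.X * (h1.s * st.H1 * (1.0 - f1) + h2.s * st.H2 * (1.0 - f2))
    return PopulationState(H1n, H2n, Pn).validate()


@dataclass(frozen=True)
class Trajectory:
    """Generation-indexed sequence of population states.

    ``states`` has shape ``(T+1, 3)`` with columns H1, H2, P;
    ``events`` maps a generation to the abundances injected at the start
    of that generation (recorded post-injection).
    """

    states: np.ndarray
    events: Mapping[int, PopulationState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InvalidParameterError(f"states must have shape (T+1, 3), got {arr.shape}")
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def generations(self) -> np.ndarray:
        return np.arange(len(self))

    @property
    def H1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def H2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 2]

    def state_at(self, t: int) -> PopulationState:
        return PopulationState(*self.states[t])

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(len(self) - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "H1": self.H1,
                "H2": self.H2,
                "P": self.P,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(states=df[["H1", "H2", "P"]].to_numpy(dtype=float))


def simulate(
    initial: PopulationState,
    params: ModelParams,
    generations: int,
    events: Mapping[int, tuple] | None = None,
) -> Trajectory:
    """Run the model for ``generations`` steps, with optional invasions.

    ``events`` maps a generation ``t`` (1 <= t <= generations) to a
    triple of abundances added to the state at the start of generation
    ``t``; the recorded state at ``t`` is post-injection and the next
    step proceeds from it.  Fully deterministic: identical inputs give
    bit-identical trajectories.
    """
    if generations < 1:
        raise InvalidParameterError(f"generations must be >= 1, got {generations!r}")
    events = dict(events or {})
    for t in events:
        if not (1 <= t <= generations):
            raise InvalidParameterError(
                f"event generation {t!r} outside [1, {generations}]"
            )
    states = np.empty((generations + 1, 3), dtype=float)
    cur = PopulationState(*initial).validate()
    states[0] = cur
    recorded_events: dict[int, PopulationState] = {}
    for t in range(1, generations + 1):
        cur = step(cur, params)
        if t in events:
            inj = PopulationState(*events[t])
            cur = cur.add(inj)
            recorded_events[t] = inj
        states[t] = cur
    return Trajectory(states=states, events=recorded_events)
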