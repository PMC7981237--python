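"""Invasion scenarios, attractor detection and indirect-interaction
classification.

Two canonical protocols are provided:

* scenario ``a`` — the unsuitable (marginal) host invades an ongoing
  suitable-host/parasitoid interaction: start ``(H1, H2, P) = (50, 0, 1)``,
  inject ``H2 += 50`` at generation 30, run to generation 100.
* scenario ``b`` — the unsuitable host is resident first: start
  ``(0, 50, 0)``, inject ``H1 += 50`` and ``P += 1`` at generation 30,
  run to generation 100.

The parasitoid-mediated indirect interaction between the two hosts is
classified from the sign of the change in each host's attractor value
when the other host is present: (+/-) apparent predation, (-/-)
apparent competition, (+/+) apparent mutualism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import Trajectory, simulate
from .params import InvalidParameterError, ModelParams, PopulationState

__all__ = [
    "ScenarioSpec",
    "AttractorSummary",
    "InteractionReport",
    "detect_attractor",
    "run_invasion_scenario",
    "classify_interaction",
]

SPECIES = ("H1", "H2", "P")

#: Default window (final generations) over which attractors are judged.
DEFAULT_WINDOW = 20
#: Relative tolerance for calling a window an equilibrium: 1e-4
#: resolves ~0.1 individual at a carrying capacity of 1000, while a
#: standard 100-generation run of a damped approach still sits ~1e-5
#: from its fixed point.
DEFAULT_TOL_EQ = 1e-4
#: Relative tolerance for period recurrence when scanning for limit
#: cycles.  Looser than the equilibrium tolerance: a marginally damped
#: cycle (e.g. the Ricker map at r = 2) recurs only to ~1e-3 within a
#: 100-generation run.
DEFAULT_TOL_CYCLE = 1e-2
#: Largest cycle period scanned for.
DEFAULT_MAX_PERIOD = 10
#: Relative dead-band below which an interaction effect counts as zero.
DEFAULT_DEADBAND = 0.01


@dataclass(frozen=True)
class ScenarioSpec:
    """An invasion protocol: initial state, injection and horizon."""

    label: str
    initial: PopulationState
    t_inv: int
    injection: PopulationState
    generations: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.t_inv <= self.generations):
            raise InvalidParameterError(
                f"need generations >= t_inv >= 1, got t_inv={self.t_inv}, "
                f"generations={self.generations}"
            )
        PopulationState(*self.initial).validate()
        inj = PopulationState(*self.injection)
        if any(v < 0 for v in inj):
            raise InvalidParameterError(f"injections must be >= 0, got {inj}")

    @classmethod
    def scenario_a(cls, invader_abundance: float = 50.0) -> "ScenarioSpec":
        """Unsuitable host invades the resident host-parasitoid system."""
        return cls(
            label="a",
            initial=PopulationState(50.0, 0.0, 1.0),
            t_inv=30,
            injection=PopulationState(0.0, invader_abundance, 0.0),
        )

    @classmethod
    def scenario_b(cls) -> "ScenarioSpec":
        """Suitable host and parasitoid invade the resident unsuitable host."""
        return cls(
            label="b",
            initial=PopulationState(0.0, 50.0, 0.0),
            t_inv=30,
            injection=PopulationState(50.0, 0.0, 1.0),
        )

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        if label == "a":
            return cls.scenario_a()
        if label == "b":
            return cls.scenario_b()
        raise InvalidParameterError(
            f"unknown scenario label {label!r}; use 'a', 'b' or a custom spec"
        )


@dataclass(frozen=True)
class AttractorSummary:
    """Outcome of attractor detection on a trajectory tail.

    Exactly one of the three statuses holds: ``equilibrium`` (all species
    constant to ``tol_eq`` over the window), ``cycle`` (recurrent with
    some period 2..max_period to ``tol_cycle``) or ``non-stationary``.
    ``value`` holds, per species, the equilibrium value or the cycle
    mean; it is ``None`` when non-stationary.
    """

    status: str
    window: int
    value: Optional[dict] = None
    period: Optional[int] = None

    @property
    def converged(self) -> bool:
        return self.status == "equilibrium"

    @property
    def cycling(self) -> bool:
        return self.status == "cycle"

    def to_dict(self) -> dict:
        return asdict(self)


def _max_rel_step(x: np.ndarray, lag: int) -> float:
    """Max relative change between states ``lag`` apart, guarded for
    near-zero abundances (absolute scale floor of 1e-9)."""
    num = np.abs(x[lag:] - x[:-lag])
    den = np.maximum(np.abs(x[:-lag]), 1e-9)
    return float(np.max(num / den)) if num.size else 0.0


def detect_attractor(
    traj: Trajectory,
    window: int = DEFAULT_WINDOW,
    tol_eq: float = DEFAULT_TOL_EQ,
    max_period: int = DEFAULT_MAX_PERIOD,
    tol_cycle: float = DEFAULT_TOL_CYCLE,
) -> AttractorSummary:
    """Classify the tail of a trajectory as equilibrium, limit cycle or
    non-stationary.

    The last ``window`` states are examined.  Equilibrium requires every
    species' successive relative changes to stay below ``tol_eq``;
    otherwise periods 2..``max_period`` are scanned for recurrence within
    ``tol_cycle`` (smallest period wins) and the cycle mean is averaged
    over the final detected period.
    """
    if window > len(traj):
        raise InvalidParameterError(
            f"window {window} exceeds trajectory length {len(traj)}"
        )
    if window < 3:
        raise InvalidParameterError(f"window must be >= 3, got {window}")
    if max_period >= window:
        raise InvalidParameterError(
            f"max_period {max_period} must be < window {window}"
        )
    tail = traj.states[-window:]

    if max(_max_rel_step(tail[:, j], 1) for j in range(3)) < tol_eq:
        value = {sp: float(np.mean(tail[:, j])) for j, sp in enumerate(SPECIES)}
        return AttractorSummary(status="equilibrium", window=window, value=value)

    for period in range(2, max_period + 1):
        if max(_max_rel_step(tail[:, j], period) for j in range(3)) < tol_cycle:
            cycle = tail[-period:]
            value = {sp: float(np.mean(cycle[:, j])) for j, sp in enumerate(SPECIES)}
            return AttractorSummary(
                status="cycle", window=window, value=value, period=period
            )

    return AttractorSummary(status="non-stationary", window=window)


def run_invasion_scenario(spec: ScenarioSpec, params: ModelParams) -> Trajectory:
    """Simulate an invasion protocol, annotating the injection event."""
    return simulate(
        spec.initial,
        params,
        spec.generations,
        events={spec.t_inv: spec.injection},
    )


def _sign(delta_rel: float, deadband: float) -> str:
    if abs(delta_rel) < deadband:
        return "0"
    return "+" if delta_rel > 0 else "-"


_LABELS = {
    ("+", "-"): "apparent predation",
    ("-", "+"): "apparent predation",
    ("-", "-"): "apparent competition",
    ("+", "+"): "apparent mutualism",
    ("0", "0"): "neutral",
    ("+", "0"): "apparent commensalism",
    ("0", "+"): "apparent commensalism",
    ("-", "0"): "apparent amensalism",
    ("0", "-"): "apparent amensalism",
}


@dataclass(frozen=True)
class InteractionReport:
    """Signed indirect-interaction classification and effect sizes.

    ``signs`` gives, per host, the sign of the effect of the *other*
    host's presence on its attractor value; ``ratios`` gives the
    with-both over alone-with-parasitoid fold changes per species.
    """

    signs: dict
    ratios: dict
    label: str
    inconclusive: bool
    attractors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "signs": self.signs,
            "ratios": self.ratios,
            "label": self.label,
            "inconclusive": self.inconclusive,
            "attractors": {
                k: v.to_dict() if isinstance(v, AttractorSummary) else v
                for k, v in self.attractors.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _settled(summary: AttractorSummary, species: str) -> Optional[float]:
    if summary.value is None:
        return None
    return summary.value[species]


def classify_interaction(
    params: ModelParams,
    spec_both: Optional[ScenarioSpec] = None,
    generations: int = 100,
    window: int = DEFAULT_WINDOW,
    deadband: float = DEFAULT_DEADBAND,
    **detect_kwargs,
) -> InteractionReport:
    """Classify the parasitoid-mediated interaction between the hosts.

    Three simulations are compared:

    1. suitable host + parasitoid alone, from ``(50, 0, 1)``;
    2. unsuitable host alone, from ``(0, 50, 1)`` (the parasitoid is
       seeded but goes extinct when ``s2 = 0``);
    3. all three species, via ``spec_both`` (default: scenario ``a``).

    Effects are measured on equilibrium values, or cycle means when an
    attractor is a limit cycle; a relative change smaller than
    ``deadband`` counts as no effect.  If any attractor is
    non-stationary the report is flagged inconclusive and unlabeled.
    """
    spec_both = spec_both or ScenarioSpec.scenario_a()

    traj_h1 = simulate(PopulationState(50.0, 0.0, 1.0), params, generations)
    traj_h2 = simulate(PopulationState(0.0, 50.0, 1.0), params, generations)
    traj_both = run_invasion_scenario(spec_both, params)

    att = {
        "host1_with_parasitoid": detect_attractor(traj_h1, window=window, **detect_kwargs),
        "host2_alone": detect_attractor(traj_h2, window=window, **detect_kwargs),
        "all_species": detect_attractor(traj_both, window=window, **detect_kwargs),
    }

    if any(a.status == "non-stationary" for a in att.values()):
        return InteractionReport(
            signs={}, ratios={}, label="inconclusive", inconclusive=True, attractors=att
        )

    h1_alone = _settled(att["host1_with_parasitoid"], "H1")
    p_alone = _settled(att["host1_with_parasitoid"], "P")
    h2_alone = _settled(att["host2_alone"], "H2")
    h1_both = _settled(att["all_species"], "H1")
    h2_both = _settled(att["all_species"], "H2")
    p_both = _settled(att["all_species"], "P")

    def rel(both: float, alone: float) -> float:
        return (both - alone) / max(abs(alone), 1e-9)

    signs = {
        "host1": _sign(rel(h1_both, h1_alone), deadband),
        "host2": _sign(rel(h2_both, h2_alone), deadband),
    }

    def ratio(both: float, alone: float) -> Optional[float]:
        return both / alone if alone > 1e-9 else None

    ratios = {
        "host1": ratio(h1_both, h1_alone),
        "host2": ratio(h2_both, h2_alone),
        "parasitoid": ratio(p_both, p_alone),
    }
    label = _LABELS[(signs["host1"], signs["host2"])]
    return InteractionReport(
        signs=signs, ratios=ratios, label=label, inconclusive=False, attractors=att
    )
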