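"""Parameter and state containers for the 2-host/1-parasitoid model.

The model tracks a suitable host (``host1``, e.g. the soybean aphid
*Aphis glycines*), an unsuitable host (``host2``, e.g. the milkweed
aphid *Aphis nerii*) and a shared parasitoid (e.g. *Aphelinus certus*).
Each host carries Ricker density dependence (``r``, ``K``), a relative
parasitoid search rate ``a``, a susceptibility ``s`` (proportion of
parasitized hosts that yield parasitoid offspring) and a nonreproductive
loss ``mu`` (proportion of parasitized hosts killed, or with reproduction
lost, without yielding offspring).  The parasitoid carries a maximum
fecundity / egg supply ``beta``, the negative-binomial aggregation
parameter ``k_agg`` and the female fraction ``X`` among viable adults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass(frozen=True)
class HostParams:
    """Demographic and vulnerability parameters of one host species.

    Parameters
    ----------
    r : float
        Intrinsic growth rate (per-generation exponent of the Ricker map).
    K : float
        Carrying capacity (individuals), > 0.
    a : float
        Relative parasitoid search rate on this host, >= 0.
    s : float
        Susceptibility: proportion of parasitized hosts yielding
        parasitoid offspring, in [0, 1].
    mu : float
        Proportion of parasitized hosts killed (or losing reproduction)
        without yielding parasitoid offspring, in [0, 1].

    ``s + mu`` must not exceed 1, so the post-parasitism survival factor
    ``1 - (s + mu) * (1 - f)`` stays in [0, 1].
    """

    r: float
    K: float
    a: float
    s: float
    mu: float

    def __post_init__(self) -> None:
        _require(_finite(self.r), f"r must be finite, got {self.r!r}")
        _require(_finite(self.K) and self.K > 0, f"K must be > 0, got {self.K!r}")
        _require(_finite(self.a) and self.a >= 0, f"a must be >= 0, got {self.a!r}")
        _require(_finite(self.s) and 0 <= self.s <= 1, f"s must be in [0, 1], got {self.s!r}")
        _require(_finite(self.mu) and 0 <= self.mu <= 1, f"mu must be in [0, 1], got {self.mu!r}")
        _require(self.s + self.mu <= 1 + 1e-12, f"s + mu must be <= 1, got {self.s + self.mu!r}")


@dataclass(frozen=True)
class ParasitoidParams:
    """Parasitoid parameters.

    ``beta`` is the maximum per-female fecundity (eggs per generation); it
    also sets the saturation of the functional response and thereby
    encodes egg/time limitation.  ``k_agg`` is the negative-binomial
    aggregation parameter of the escape function (small values = highly
    clumped attack risk).  ``X`` is the fraction of viable emerging
    adults that are female.
    """

    beta: float
    k_agg: float
    X: float

    def __post_init__(self) -> None:
        _require(_finite(self.beta) and self.beta > 0, f"beta must be > 0, got {self.beta!r}")
        _require(_finite(self.k_agg) and self.k_agg > 0, f"k_agg must be > 0, got {self.k_agg!r}")
        _require(_finite(self.X) and 0 <= self.X <= 1, f"X must be in [0, 1], got {self.X!r}")


# Flat config keys accepted in parameter files, in canonical order.
FLAT_KEYS = ("a1", "a2", "r1", "r2", "K1", "K2", "s1", "s2", "mu1", "mu2", "beta", "k", "X")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: two hosts plus the shared parasitoid."""

    host1: HostParams
    host2: HostParams
    parasitoid: ParasitoidParams = field(
        default_factory=lambda: ParasitoidParams(beta=16.0, k_agg=0.75, X=0.29)
    )

    @classmethod
    def paper_defaults(cls) -> "ModelParams":
        """Default parameterization of the soybean-aphid / milkweed-aphid /
        *A. certus* system: a1=1, a2=0.45, r=2, K=1000, beta=16, s1=1,
        s2=0, mu1=0, mu2=0.4, k=0.75, X=0.29."""
        return cls(
            host1=HostParams(r=2.0, K=1000.0, a=1.0, s=1.0, mu=0.0),
            host2=HostParams(r=2.0, K=1000.0, a=0.45, s=0.0, mu=0.4),
            parasitoid=ParasitoidParams(beta=16.0, k_agg=0.75, X=0.29),
        )

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ModelParams":
        """Build from a flat mapping with keys a1,a2,r1,r2,K1,K2,s1,s2,
        mu1,mu2,beta,k,X.  Keys starting with ``_`` are ignored (metadata);
        any other unknown key raises :class:`InvalidParameterError`."""
        clean = {k: v for k, v in d.items() if not str(k).startswith("_")}
        unknown = set(clean) - set(FLAT_KEYS)
        _require(not unknown, f"unknown parameter key(s): {sorted(unknown)}")
        missing = set(FLAT_KEYS) - set(clean)
        _require(not missing, f"missing parameter key(s): {sorted(missing)}")
        vals = {k: float(clean[k]) for k in FLAT_KEYS}
        return cls(
            host1=HostParams(r=vals["r1"], K=vals["K1"], a=vals["a1"], s=vals["s1"], mu=vals["mu1"]),
            host2=HostParams(r=vals["r2"], K=vals["K2"], a=vals["a2"], s=vals["s2"], mu=vals["mu2"]),
            parasitoid=ParasitoidParams(beta=vals["beta"], k_agg=vals["k"], X=vals["X"]),
        )

    def to_flat_dict(self) -> dict:
        h1, h2, p = self.host1, self.host2, self.parasitoid
        return {
            "a1": h1.a, "a2": h2.a, "r1": h1.r, "r2": h2.r,
            "K1": h1.K, "K2": h2.K, "s1": h1.s, "s2": h2.s,
            "mu1": h1.mu, "mu2": h2.mu,
            "beta": p.beta, "k": p.k_agg, "X": p.X,
        }

    def host(self, index: int) -> HostParams:
        if index == 1:
            return self.host1
        if index == 2:
            return self.host2
        raise InvalidParameterError(f"host index must be 1 or 2, got {index!r}")


class PopulationState(NamedTuple):
    """Abundances at one generation (continuous-valued, >= 0)."""

    H1: float
    H2: float
    P: float

    def validate(self) -> "PopulationState":
        for name, v in zip(self._fields, self):
            _require(_finite(v) and v >= 0, f"{name} must be finite and >= 0, got {v!r}")
        return self

    def add(self, other: "PopulationState | tuple") -> "PopulationState":
        """Additive invasion injection."""
        o = PopulationState(*other)
        for name, v in zip(o._fields, o):
            _require(_finite(v) and v >= 0, f"injection {name} must be >= 0, got {v!r}")
        return PopulationState(self.H1 + o.H1, self.H2 + o.H2, self.P + o.P)
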