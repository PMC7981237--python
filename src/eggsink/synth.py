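"""Seeded synthetic microcosm data with the statistical structure of the
three laboratory assays (oviposition choice/no-choice tubes, whole-plant
development arenas, and daily survival/fecundity observations of
parasitized vs unparasitized unsuitable hosts).

Every generator is a pure function of its :class:`GeneratorConfig`
(which carries the seed): repeated calls return identical tables.

Generative model
----------------
A female parasitoid carries an egg supply S drawn from a bounded
complement, by default ``Binomial(supply_cap, mean/cap)`` — the egg
complement of a small synovigenic wasp is capped by its ovariole
number, which also keeps between-female variance realistic and low.
``supply_dist`` switches to ``"poisson"`` or, with
``overdispersion_k`` set, a negative-binomial.

Eggs are allocated between host species in proportion to attack
weights ``(ratio * d1) : (1 * d2)`` (densities d, suitable:unsuitable
attack ratio as configured), scaled by a treatment-level lay fraction.
With the default ``"quota"`` allocation a female deposits the expected
share up to integer rounding (floor plus a Bernoulli remainder); the
``"multinomial"`` switch draws egg-by-egg multinomial allocations
instead.  Residual eggs are the undeposited remainder, so
laid + residual always equals the supply.

Development replicates push the allocated eggs through a chain of
binomials: parasitized -> mummies (species-specific mummification) ->
emerged (viability) -> females (sex ratio).  Survival replicates draw a
geometric lifetime (discrete daily hazard) per aphid and Poisson daily
nymph production after a fixed pre-reproductive period, with the daily
mean back-computed so each group's expected lifetime fecundity matches
its configured target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .params import InvalidParameterError

__all__ = [
    "GeneratorConfig",
    "generate_oviposition_assay",
    "generate_development_assay",
    "generate_survival_fecundity_assay",
    "generate_egg_load_tibia",
    "generate_study",
]

#: treatment -> (suitable hosts, unsuitable hosts) in the oviposition tubes
OVI_DENSITIES = {
    "no-choice-suitable": (20, 0),
    "no-choice-unsuitable": (0, 20),
    "choice-low": (10, 10),
    "choice-high": (20, 20),
}
#: treatment -> densities on the potted plants of the development assay
DEV_DENSITIES = {
    "no-choice-suitable": (50, 0),
    "no-choice-unsuitable": (0, 50),
    "choice-low": (25, 25),
    "choice-high": (50, 50),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration (truth) of the synthetic study.

    Defaults reproduce the study conditions: 25 replicates per
    treatment, 20-host tubes (10+10 / 20+20 in choice), a 2.2:1
    suitable:unsuitable attack ratio, egg supply with mean 16, 0.6
    emergence x 0.48 female share, near-zero unsuitable-host
    mummification, 37 parasitized / 33 control aphids with a 1.4-fold
    longevity reduction and lifetime fecundities targeting 30.7 vs 12.2
    nymphs, a 7-day pre-reproductive period, and an egg-load ~ tibia
    regression Y = 164.79 x - 24.68 with R^2 = 0.39.
    """

    seed: int = 0
    # --- replicate structure ---
    n_replicates: dict = field(
        default_factory=lambda: {t: 25 for t in OVI_DENSITIES}
    )
    # --- egg supply ---
    supply_mean: float = 16.0
    supply_dist: str = "binomial"  # binomial | poisson | negbin
    supply_cap: int = 20
    overdispersion_k: float = 5.0  # negbin shape when supply_dist == "negbin"
    # --- oviposition behavior ---
    attack_ratio: float = 2.2  # suitable : unsuitable
    lay_fraction_oviposition: float = 0.625  # tubes, 24 h
    lay_fraction_development: float = 0.95  # whole plants, more hosts
    allocation: str = "quota"  # quota | multinomial
    # --- development chain ---
    mummification_suitable: float = 0.95
    mummification_unsuitable: float = 0.0
    emergence_rate: float = 0.6
    female_share: float = 0.48
    # --- survival / fecundity (unsuitable host) ---
    n_parasitized: int = 37
    n_control: int = 33
    longevity_mean_control: float = 28.0
    longevity_mean_parasitized: float = 20.0  # 1.4-fold reduction
    fecundity_target_control: float = 30.7
    fecundity_target_parasitized: float = 12.2
    prereproductive_days: int = 7
    # --- tibia / egg load ---
    tibia_mean_mm: float = 0.25
    tibia_sd_mm: float = 0.02
    egg_load_slope: float = 164.79
    egg_load_intercept: float = -24.68
    egg_load_r2: float = 0.39

    def __post_init__(self) -> None:
        probs = (
            self.emergence_rate, self.female_share,
            self.mummification_suitable, self.mummification_unsuitable,
            self.lay_fraction_oviposition, self.lay_fraction_development,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise InvalidParameterError(f"probabilities must be in [0, 1]: {probs}")
        if self.supply_mean < 0 or self.attack_ratio < 0:
            raise InvalidParameterError("means and ratios must be >= 0")
        if self.attack_ratio == 0 and all(d[0] == 0 for d in OVI_DENSITIES.values()):
            raise InvalidParameterError("attack weights are zero for both species")
        if any(n < 1 for n in self.n_replicates.values()):
            raise InvalidParameterError("replicate counts must be >= 1")
        if self.supply_dist not in ("binomial", "poisson", "negbin"):
            raise InvalidParameterError(f"unknown supply_dist {self.supply_dist!r}")
        if self.allocation not in ("quota", "multinomial"):
            raise InvalidParameterError(f"unknown allocation {self.allocation!r}")
        if not (0.0 < self.egg_load_r2 < 1.0):
            raise InvalidParameterError("egg_load_r2 must be in (0, 1)")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        clean = {k: v for k, v in d.items() if not str(k).startswith("_")}
        unknown = set(clean) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown generator key(s): {sorted(unknown)}")
        return cls(**clean)

    @classmethod
    def paper_like(cls, seed: int = 0) -> "GeneratorConfig":
        """The default study conditions (see class docstring)."""
        return cls(seed=seed)


#: Stable sub-stream ids so each assay gets an independent deterministic RNG.
_STREAMS = {"oviposition": 1, "development": 2, "survival": 3, "egg_load": 4}


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per assay, derived from the seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


def _draw_supply(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    m = config.supply_mean
    if config.supply_dist == "binomial":
        cap = max(config.supply_cap, int(math.ceil(m)))
        return rng.binomial(cap, m / cap, size=n)
    if config.supply_dist == "poisson":
        return rng.poisson(m, size=n)
    k = config.overdispersion_k
    return rng.negative_binomial(k, k / (k + m), size=n)


def _quota_round(rng: np.random.Generator, x: float) -> int:
    base = math.floor(x)
    return base + int(rng.random() < (x - base))


def _allocate_eggs(
    rng: np.random.Generator,
    config: GeneratorConfig,
    supply: int,
    densities: tuple[int, int],
    lay_fraction: float,
) -> tuple[int, int]:
    """Eggs deposited into (suitable, unsuitable) hosts by one female."""
    d1, d2 = densities
    w1, w2 = config.attack_ratio * d1, 1.0 * d2
    wsum = w1 + w2
    if wsum == 0:
        return 0, 0
    # Reference weight: the egg-laying drive if all hosts were of the
    # preferred species.  A no-choice unsuitable tube therefore realizes
    # only 1/ratio of the configured lay fraction, reproducing the
    # no-choice egg-deposition ratio between the species.
    wref = max(wsum, config.attack_ratio * max(d1, d2))
    p1 = lay_fraction * (w1 / wref)
    p2 = lay_fraction * (w2 / wref)
    if config.allocation == "multinomial":
        draws = rng.multinomial(supply, [p1, p2, max(0.0, 1.0 - p1 - p2)])
        return int(draws[0]), int(draws[1])
    laid1 = _quota_round(rng, supply * p1)
    laid2 = _quota_round(rng, supply * p2)
    excess = laid1 + laid2 - supply
    if excess > 0:  # cap at the available complement
        take2 = min(excess, laid2)
        laid2 -= take2
        laid1 -= excess - take2
    return laid1, laid2


def _tibia(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    return rng.normal(config.tibia_mean_mm, config.tibia_sd_mm, size=n)


def generate_oviposition_assay(config: GeneratorConfig) -> pd.DataFrame:
    """Per-replicate egg deposition table (oviposition schema)."""
    rng = _rng(config, "oviposition")
    rows = []
    for treatment, densities in OVI_DENSITIES.items():
        n_rep = config.n_replicates[treatment]
        supplies = _draw_supply(rng, config, n_rep)
        tibias = _tibia(rng, config, n_rep)
        for rep in range(1, n_rep + 1):
            supply = int(supplies[rep - 1])
            laid1, laid2 = _allocate_eggs(
                rng, config, supply, densities, config.lay_fraction_oviposition
            )
            residual = supply - laid1 - laid2
            for species, laid, dens in (
                ("suitable", laid1, densities[0]),
                ("unsuitable", laid2, densities[1]),
            ):
                if dens == 0:
                    continue
                rows.append(
                    {
                        "replicate": rep,
                        "treatment": treatment,
                        "species": species,
                        "eggs_laid": laid,
                        "residual_eggs": residual,
                        "tibia_mm": round(float(tibias[rep - 1]), 4),
                    }
                )
    return pd.DataFrame(rows)


def generate_development_assay(config: GeneratorConfig) -> pd.DataFrame:
    """Per-replicate mummy / emergence / sex-ratio table (development schema)."""
    rng = _rng(config, "development")
    mumm = {
        "suitable": config.mummification_suitable,
        "unsuitable": config.mummification_unsuitable,
    }
    rows = []
    for treatment, densities in DEV_DENSITIES.items():
        n_rep = config.n_replicates[treatment]
        supplies = _draw_supply(rng, config, n_rep)
        tibias = _tibia(rng, config, n_rep)
        for rep in range(1, n_rep + 1):
            supply = int(supplies[rep - 1])
            laid1, laid2 = _allocate_eggs(
                rng, config, supply, densities, config.lay_fraction_development
            )
            residual = supply - laid1 - laid2
            for species, laid, dens in (
                ("suitable", laid1, densities[0]),
                ("unsuitable", laid2, densities[1]),
            ):
                if dens == 0:
                    continue
                parasitized = min(laid, dens)  # superparasitized eggs are wasted
                mummies = int(rng.binomial(parasitized, mumm[species]))
                emerged = int(rng.binomial(mummies, config.emergence_rate))
                females = int(rng.binomial(emerged, config.female_share))
                rows.append(
                    {
                        "replicate": rep,
                        "treatment": treatment,
                        "species": species,
                        "mummies": mummies,
                        "emerged": emerged,
                        "females": females,
                        "residual_eggs": residual,
                        "tibia_mm": round(float(tibias[rep - 1]), 4),
                    }
                )
    return pd.DataFrame(rows)


def _daily_fecundity(mean_longevity: float, target: float, prerep: int) -> float:
    """Daily nymph mean giving the target expected lifetime fecundity
    under a geometric lifetime: E[max(0, L - prerep)] = mean*(1-1/mean)^prerep."""
    reproductive_days = mean_longevity * (1.0 - 1.0 / mean_longevity) ** prerep
    return target / reproductive_days


def generate_survival_fecundity_assay(config: GeneratorConfig) -> pd.DataFrame:
    """Daily survival / nymph-production records (survival schema)."""
    rng = _rng(config, "survival")
    groups = {
        "parasitized": (
            config.n_parasitized,
            config.longevity_mean_parasitized,
            config.fecundity_target_parasitized,
        ),
        "control": (
            config.n_control,
            config.longevity_mean_control,
            config.fecundity_target_control,
        ),
    }
    prerep = config.prereproductive_days
    rows = []
    aphid_id = 0
    for group, (n, mean_longevity, fec_target) in groups.items():
        if mean_longevity <= 1:
            raise InvalidParameterError("longevity means must exceed 1 day")
        daily = _daily_fecundity(mean_longevity, fec_target, prerep)
        lifetimes = rng.geometric(1.0 / mean_longevity, size=n)
        for i in range(n):
            aphid_id += 1
            lifetime = int(lifetimes[i])
            for day in range(1, lifetime + 1):
                nymphs = int(rng.poisson(daily)) if day > prerep else 0
                rows.append(
                    {
                        "aphid_id": aphid_id,
                        "group": group,
                        "day": day,
                        "nymphs": nymphs,
                        "alive": 1,
                    }
                )
            rows.append(
                {
                    "aphid_id": aphid_id,
                    "group": group,
                    "day": lifetime + 1,
                    "nymphs": 0,
                    "alive": 0,
                }
            )
    return pd.DataFrame(rows)


def generate_egg_load_tibia(config: GeneratorConfig, n: int) -> pd.DataFrame:
    """Table of (tibia_mm, egg_load) reproducing the egg-load ~ tibia
    regression: the linear signal plus Gaussian noise whose variance is
    set from the configured population R^2
    (``noise_var = signal_var * (1/R^2 - 1)``)."""
    if n < 2:
        raise InvalidParameterError(f"need n >= 2, got {n}")
    rng = _rng(config, "egg_load")
    x = _tibia(rng, config, n)
    signal_var = (config.egg_load_slope * config.tibia_sd_mm) ** 2
    noise_sd = math.sqrt(signal_var * (1.0 / config.egg_load_r2 - 1.0))
    y = config.egg_load_slope * x + config.egg_load_intercept
    y = y + rng.normal(0.0, noise_sd, size=n)
    egg_load = np.round(np.maximum(0.0, y)).astype(int)
    return pd.DataFrame({"tibia_mm": np.round(x, 4), "egg_load": egg_load})


def generate_study(config: GeneratorConfig) -> dict:
    """All three assay tables for one seeded synthetic study."""
    return {
        "oviposition": generate_oviposition_assay(config),
        "development": generate_development_assay(config),
        "survival": generate_survival_fecundity_assay(config),
    }
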