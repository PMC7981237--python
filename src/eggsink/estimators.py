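"""Estimators mapping microcosm assay tables to model parameters.

Three tidy CSV schemas are consumed (see also :mod:`eggsink.synth`,
which generates them):

* oviposition assay — ``replicate,treatment,species,eggs_laid,
  residual_eggs,tibia_mm``; one row per replicate x host species, with
  the female-level residual egg load and tibia length repeated on each
  row of the replicate.
* development assay — ``replicate,treatment,species,mummies,emerged,
  females,residual_eggs,tibia_mm``.
* survival/fecundity assay — ``aphid_id,group,day,nymphs,alive``; one
  row per aphid per day alive.

Treatments come from the fixed set ``no-choice-suitable``,
``no-choice-unsuitable``, ``choice-low``, ``choice-high``; species are
``suitable`` / ``unsuitable``; groups are ``parasitized`` / ``control``.

Estimators pool counts across replicates (ratios of sums) rather than
averaging per-replicate ratios, avoiding small-denominator instability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import pandas as pd

from .params import ModelParams, HostParams, ParasitoidParams

__all__ = [
    "TREATMENTS",
    "SPECIES_LEVELS",
    "GROUPS",
    "InsufficientDataError",
    "UndefinedRatioError",
    "EstimatedParams",
    "estimate_relative_search_rate",
    "estimate_nonreproductive_impact",
    "estimate_sex_ratio",
    "estimate_beta",
    "estimate_susceptibility",
    "estimate_all",
]

TREATMENTS = (
    "no-choice-suitable",
    "no-choice-unsuitable",
    "choice-low",
    "choice-high",
)
SPECIES_LEVELS = ("suitable", "unsuitable")
GROUPS = ("parasitized", "control")

#: Minimum mummies per replicate for emergence / sex-ratio estimation.
MIN_MUMMIES = 10


class InsufficientDataError(ValueError):
    """Raised when an assay lacks the rows an estimator needs."""


class UndefinedRatioError(ValueError):
    """Raised when a ratio estimator's denominator is zero."""


def _check_columns(df: pd.DataFrame, cols: tuple, what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise InsufficientDataError(f"{what} assay missing column(s): {sorted(missing)}")


def estimate_relative_search_rate(oviposition: pd.DataFrame) -> float:
    """Relative search rate ``a2/a1`` from no-choice egg deposition.

    The ratio of mean eggs laid per replicate into the unsuitable host
    to the mean laid into the suitable host, each from its own no-choice
    treatment.  A suitable:unsuitable egg ratio of 2.2 yields
    ``a_rel = 1/2.2 ~= 0.45``.
    """
    _check_columns(oviposition, ("treatment", "species", "eggs_laid"), "oviposition")
    means = {}
    for treatment, species in (
        ("no-choice-suitable", "suitable"),
        ("no-choice-unsuitable", "unsuitable"),
    ):
        sub = oviposition[
            (oviposition["treatment"] == treatment)
            & (oviposition["species"] == species)
        ]
        if sub.empty:
            raise InsufficientDataError(f"no rows for treatment {treatment!r}")
        means[species] = sub["eggs_laid"].sum() / sub["replicate"].nunique()
    if means["suitable"] <= 0:
        raise UndefinedRatioError("mean eggs laid into suitable host is zero")
    return float(means["unsuitable"] / means["suitable"])


def estimate_nonreproductive_impact(survival: pd.DataFrame) -> float:
    """Nonreproductive parasitism cost ``mu`` from lifetime fecundity.

    ``mu_hat = 1 - (mean lifetime fecundity, parasitized) / (mean,
    control)``, clamped to [0, 1].  Longevity enters only through its
    effect on lifetime fecundity.
    """
    _check_columns(survival, ("aphid_id", "group", "nymphs"), "survival")
    fec = (
        survival.groupby(["group", "aphid_id"], observed=True)["nymphs"]
        .sum()
        .groupby("group", observed=True)
        .agg(["mean", "size"])
    )
    for group in GROUPS:
        if group not in fec.index or fec.loc[group, "size"] < 2:
            raise InsufficientDataError(f"need >= 2 aphids in group {group!r}")
    control = float(fec.loc["control", "mean"])
    parasitized = float(fec.loc["parasitized", "mean"])
    if control <= 0:
        raise UndefinedRatioError("control lifetime fecundity is zero")
    return float(min(1.0, max(0.0, 1.0 - parasitized / control)))


def estimate_sex_ratio(
    development: pd.DataFrame, min_mummies: int = MIN_MUMMIES
) -> float:
    """Effective female recruitment fraction ``X``.

    Pooled over suitable-host replicates with at least ``min_mummies``
    mummies: total emerged females divided by total mummies, i.e. the
    emergence (viability) rate folded into the female share among
    emerged adults.  With emergence 0.6 and female share 0.48,
    ``X ~= 0.29``.
    """
    _check_columns(development, ("replicate", "species", "mummies", "females"), "development")
    sub = development[development["species"] == "suitable"]
    qual = sub[sub["mummies"] >= min_mummies]
    if qual.empty:
        raise InsufficientDataError(
            f"no suitable-host replicates with >= {min_mummies} mummies"
        )
    return float(qual["females"].sum() / qual["mummies"].sum())


def estimate_beta(oviposition: pd.DataFrame) -> int:
    """Maximum daily fecundity ``beta``: mean total egg supply per female.

    For every female with a residual egg count, supply = eggs deposited
    over 24 h (all species) + residual eggs at dissection; ``beta_hat``
    is the mean over females, rounded to the nearest integer.  Pools all
    treatments, since the egg complement is a property of the female,
    but requires the no-choice suitable treatment to be present.
    """
    _check_columns(oviposition, ("replicate", "treatment", "eggs_laid", "residual_eggs"), "oviposition")
    if not (oviposition["treatment"] == "no-choice-suitable").any():
        raise InsufficientDataError("no-choice suitable-host treatment absent")
    per_female = oviposition.groupby(["treatment", "replicate"], observed=True).agg(
        laid=("eggs_laid", "sum"), residual=("residual_eggs", "first")
    )
    per_female = per_female.dropna(subset=["residual"])
    if per_female.empty:
        raise InsufficientDataError("no residual-egg records in oviposition assay")
    supply = per_female["laid"] + per_female["residual"]
    return int(round(float(supply.mean())))


def _snap_extreme(value: float, snap_tol: float) -> float:
    if value <= snap_tol:
        return 0.0
    if value >= 1.0 - snap_tol:
        return 1.0
    return value


def estimate_susceptibility(
    development: pd.DataFrame,
    oviposition: pd.DataFrame,
    hosts_exposed: int = 50,
    snap: bool = False,
    snap_tol: float = 0.25,
) -> tuple[float, float]:
    """Susceptibilities ``(s1, s2)``: offspring-producing mummies per
    parasitized host, per species.

    The numerator pools emerged adults over no-choice development
    replicates.  The number of parasitized hosts per replicate is not
    observed directly and is approximated by the per-female mean
    no-choice egg deposition from the oviposition assay, capped at
    ``hosts_exposed``.  Estimates are clamped to [0, 1]; with
    ``snap=True`` values within ``snap_tol`` of 0 or 1 are snapped to
    the endpoint (a fully suitable or fully unsuitable host).
    """
    _check_columns(development, ("replicate", "treatment", "species", "emerged"), "development")
    _check_columns(oviposition, ("replicate", "treatment", "species", "eggs_laid"), "oviposition")
    out = []
    for species, treatment in (
        ("suitable", "no-choice-suitable"),
        ("unsuitable", "no-choice-unsuitable"),
    ):
        dev = development[
            (development["treatment"] == treatment) & (development["species"] == species)
        ]
        ovi = oviposition[
            (oviposition["treatment"] == treatment) & (oviposition["species"] == species)
        ]
        if dev.empty or ovi.empty:
            raise InsufficientDataError(f"no-choice data absent for {species!r} host")
        eggs_per_female = ovi["eggs_laid"].sum() / ovi["replicate"].nunique()
        parasitized_per_rep = min(eggs_per_female, float(hosts_exposed))
        if parasitized_per_rep <= 0:
            raise InsufficientDataError(f"zero parasitized {species!r} hosts")
        est = dev["emerged"].sum() / (parasitized_per_rep * dev["replicate"].nunique())
        est = min(1.0, max(0.0, float(est)))
        out.append(_snap_extreme(est, snap_tol) if snap else est)
    return out[0], out[1]


@dataclass(frozen=True)
class EstimatedParams:
    """Assay-derived model parameters with the sample sizes used."""

    a_rel: float
    beta: int
    X: float
    s1: float
    s2: float
    mu2: float
    n_oviposition: int
    n_development: int
    n_survival: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_model_params(
        self, base: Optional[ModelParams] = None
    ) -> ModelParams:
        """Combine with a base parameterization (default: the packaged
        defaults) for the quantities no assay informs (r, K, k, a1, mu1)."""
        base = base or ModelParams.paper_defaults()
        return ModelParams(
            host1=HostParams(
                r=base.host1.r, K=base.host1.K, a=base.host1.a,
                s=self.s1, mu=min(base.host1.mu, 1.0 - self.s1),
            ),
            host2=HostParams(
                r=base.host2.r, K=base.host2.K, a=self.a_rel * base.host1.a,
                s=self.s2, mu=min(self.mu2, 1.0 - self.s2),
            ),
            parasitoid=ParasitoidParams(
                beta=float(self.beta), k_agg=base.parasitoid.k_agg, X=self.X
            ),
        )

    def to_flat_config(self, base: Optional[ModelParams] = None) -> dict:
        """Flat model config (round-trips through ModelParams.from_flat_dict)
        with the estimation sample sizes under a ``_estimation`` key."""
        cfg = self.to_model_params(base).to_flat_dict()
        cfg["a2"] = round(cfg["a2"], 2)
        cfg["_estimation"] = {
            "a_rel": round(self.a_rel, 2),
            "beta": self.beta,
            "X": round(self.X, 4),
            "s1": round(self.s1, 4),
            "s2": round(self.s2, 4),
            "mu2": round(self.mu2, 4),
            "n_oviposition": self.n_oviposition,
            "n_development": self.n_development,
            "n_survival": self.n_survival,
        }
        return cfg


def estimate_all(
    oviposition: pd.DataFrame,
    development: pd.DataFrame,
    survival: pd.DataFrame,
    hosts_exposed: int = 50,
    snap_susceptibility: bool = True,
) -> EstimatedParams:
    """Run the full estimation pipeline on the three assay tables."""
    beta = estimate_beta(oviposition)
    if beta <= 0:
        raise UndefinedRatioError(
            "estimated beta is 0, below the model's beta > 0 bound"
        )
    s1, s2 = estimate_susceptibility(
        development, oviposition, hosts_exposed=hosts_exposed, snap=snap_susceptibility
    )
    return EstimatedParams(
        a_rel=estimate_relative_search_rate(oviposition),
        beta=beta,
        X=estimate_sex_ratio(development),
        s1=s1,
        s2=s2,
        mu2=estimate_nonreproductive_impact(survival),
        n_oviposition=int(oviposition["replicate"].nunique()),
        n_development=int(development["replicate"].nunique()),
        n_survival=int(survival["aphid_id"].nunique()),
    )
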