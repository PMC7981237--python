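import numpy as np
import pandas as pd
import pytest

from eggsink import (
    InsufficientDataError,
    UndefinedRatioError,
    estimate_all,
    estimate_beta,
    estimate_nonreproductive_impact,
    estimate_relative_search_rate,
    estimate_sex_ratio,
    estimate_susceptibility,
)


def oviposition_table(suitable_eggs, unsuitable_eggs, residual=6, tibia=0.25):
    """No-choice oviposition assay with the given per-replicate egg counts."""
    rows = []
    for treatment, species, eggs in (
        ("no-choice-suitable", "suitable", suitable_eggs),
        ("no-choice-unsuitable", "unsuitable", unsuitable_eggs),
    ):
        for rep, e in enumerate(eggs, start=1):
            rows.append(
                dict(replicate=rep, treatment=treatment, species=species,
                     eggs_laid=e, residual_eggs=residual, tibia_mm=tibia)
            )
    return pd.DataFrame(rows)


def development_table(mummies, emerged, females, species="suitable",
                      treatment="no-choice-suitable"):
    return pd.DataFrame(
        [
            dict(replicate=rep, treatment=treatment, species=species,
                 mummies=m, emerged=e, females=f, residual_eggs=2, tibia_mm=0.25)
            for rep, (m, e, f) in enumerate(zip(mummies, emerged, females), start=1)
        ]
    )


def survival_table(parasitized_fecundities, control_fecundities):
    """One-day-per-nymph-batch survival records with given lifetime sums."""
    rows = []
    aphid = 0
    for group, fecs in (
        ("parasitized", parasitized_fecundities),
        ("control", control_fecundities),
    ):
        for total in fecs:
            aphid += 1
            rows.append(dict(aphid_id=aphid, group=group, day=8, nymphs=total, alive=1))
            rows.append(dict(aphid_id=aphid, group=group, day=9, nymphs=0, alive=0))
    return pd.DataFrame(rows)


class TestRelativeSearchRate:
    def test_identical_attack_gives_unity(self):
        ovi = oviposition_table([8, 10, 12], [10, 10, 10])
        assert estimate_relative_search_rate(ovi) == pytest.approx(1.0)

    def test_printed_egg_ratio_reproduces_search_rate(self):
        """A 2.2-fold no-choice egg ratio maps to a2/a1 = 1/2.2 ~ 0.45."""
        ovi = oviposition_table([22, 22], [10, 10])
        a_rel = estimate_relative_search_rate(ovi)
        assert round(a_rel, 2) == 0.45

    def test_zero_suitable_mean_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            estimate_relative_search_rate(oviposition_table([0, 0], [5, 5]))

    def test_missing_treatment_is_insufficient(self):
        ovi = oviposition_table([10], [5])
        only_suitable = ovi[ovi.treatment == "no-choice-suitable"]
        with pytest.raises(InsufficientDataError):
            estimate_relative_search_rate(only_suitable)

    def test_invariant_under_replicate_duplication(self):
        ovi = oviposition_table([9, 11, 13], [4, 5, 6])
        dup = ovi.copy()
        dup["replicate"] += 100
        doubled = pd.concat([ovi, dup], ignore_index=True)
        assert estimate_relative_search_rate(doubled) == pytest.approx(
            estimate_relative_search_rate(ovi)
        )


class TestNonreproductiveImpact:
    def test_equal_fecundity_means_no_cost(self):
        surv = survival_table([30, 31], [31, 30])
        assert estimate_nonreproductive_impact(surv) == pytest.approx(0.0)

    def test_printed_group_means(self):
        """Parasitized 12.2 vs control 30.7 offspring: 1 - 12.2/30.7 ~ 0.60."""
        surv = survival_table([12, 12, 12, 13], [30, 31, 31, 31])
        mu = estimate_nonreproductive_impact(surv)
        assert mu == pytest.approx(1 - 12.25 / 30.75, rel=1e-12)

    def test_complete_sterilization(self):
        surv = survival_table([0, 0], [20, 25])
        assert estimate_nonreproductive_impact(surv) == 1.0

    def test_zero_control_fecundity_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            estimate_nonreproductive_impact(survival_table([0, 0], [0, 0]))

    def test_antitone_in_parasitized_fecundity(self):
        controls = [30, 30, 30]
        values = [
            estimate_nonreproductive_impact(survival_table([f, f, f], controls))
            for f in (0, 5, 10, 20, 30)
        ]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_single_aphid_group_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_nonreproductive_impact(survival_table([10], [20, 21]))


class TestSexRatio:
    def test_all_mummies_emerge_female(self):
        dev = development_table([20, 15], [20, 15], [20, 15])
        assert estimate_sex_ratio(dev) == 1.0

    def test_definitional_arithmetic(self):
        dev = development_table([40, 60], [20, 40], [10, 20])
        assert estimate_sex_ratio(dev) == pytest.approx(0.30)

    def test_low_mummy_replicates_excluded(self):
        dev = development_table([40, 5], [20, 5], [10, 5])
        # the 5-mummy replicate is below the >= 10 cutoff
        assert estimate_sex_ratio(dev) == pytest.approx(10 / 40)

    def test_no_qualifying_replicates(self):
        with pytest.raises(InsufficientDataError):
            estimate_sex_ratio(development_table([5, 8], [5, 8], [2, 3]))


class TestBeta:
    def test_constant_supply(self):
        ovi = oviposition_table([10, 10], [4, 4], residual=6)
        # suitable females: 10+6; unsuitable females: 4+6; mean = 13
        assert estimate_beta(ovi) == 13

    def test_degenerate_zero_supply(self):
        ovi = oviposition_table([0, 0], [0, 0], residual=0)
        assert estimate_beta(ovi) == 0
        with pytest.raises(UndefinedRatioError, match="beta"):
            estimate_all(
                ovi,
                development_table([20], [12], [6]),
                survival_table([10, 10], [20, 20]),
            )

    def test_missing_residuals_is_insufficient(self):
        ovi = oviposition_table([10, 10], [4, 4], residual=np.nan)
        with pytest.raises(InsufficientDataError):
            estimate_beta(ovi)


class TestSusceptibility:
    def _dev_both_species(self, emerged_suitable, emerged_unsuitable):
        suit = development_table(
            [e + 2 for e in emerged_suitable], emerged_suitable,
            [0] * len(emerged_suitable),
        )
        unsuit = development_table(
            [0] * len(emerged_unsuitable), emerged_unsuitable,
            [0] * len(emerged_unsuitable),
            species="unsuitable", treatment="no-choice-unsuitable",
        )
        return pd.concat([suit, unsuit], ignore_index=True)

    def test_unsuitable_host_with_eggs_but_no_mummies(self):
        dev = self._dev_both_species([10, 10], [0, 0])
        ovi = oviposition_table([20, 20], [9, 9])
        s1, s2 = estimate_susceptibility(dev, ovi)
        assert s2 == 0.0
        assert s1 == pytest.approx(0.5)

    def test_full_success_is_one(self):
        dev = self._dev_both_species([20, 20], [0, 0])
        ovi = oviposition_table([20, 20], [9, 9])
        s1, _ = estimate_susceptibility(dev, ovi)
        assert s1 == 1.0

    def test_definitional_arithmetic(self):
        # 40 parasitized hosts, 30 offspring-producing mummies -> 0.75
        dev = self._dev_both_species([30], [0])
        ovi = oviposition_table([40], [5])
        s1, _ = estimate_susceptibility(dev, ovi)
        assert s1 == pytest.approx(0.75)

    def test_parasitized_hosts_capped_at_exposure(self):
        dev = self._dev_both_species([30], [0])
        ovi = oviposition_table([80], [5])
        s1, _ = estimate_susceptibility(dev, ovi, hosts_exposed=50)
        assert s1 == pytest.approx(30 / 50)

    def test_snapping_only_near_endpoints(self):
        dev = self._dev_both_species([36], [0])
        ovi = oviposition_table([40], [5])
        s1_raw, s2_raw = estimate_susceptibility(dev, ovi, snap=False)
        s1_snap, s2_snap = estimate_susceptibility(dev, ovi, snap=True)
        assert s1_raw == pytest.approx(0.9)
        assert s1_snap == 1.0
        assert s2_raw == s2_snap == 0.0

    def test_zero_eggs_is_insufficient(self):
        dev = self._dev_both_species([10], [0])
        ovi = oviposition_table([0], [0])
        with pytest.raises(InsufficientDataError):
            estimate_susceptibility(dev, ovi)


class TestEstimateAll:
    def test_bundles_all_parameters_with_sample_sizes(self):
        ovi = oviposition_table([22, 22, 22], [10, 10, 10], residual=4)
        dev = pd.concat(
            [
                development_table([20, 18, 20], [12, 11, 12], [6, 5, 6]),
                development_table(
                    [0, 0, 0], [0, 0, 0], [0, 0, 0],
                    species="unsuitable", treatment="no-choice-unsuitable",
                ),
            ],
            ignore_index=True,
        )
        surv = survival_table([12, 12, 13, 12], [30, 31, 31, 31])
        est = estimate_all(ovi, dev, surv)
        assert round(est.a_rel, 2) == 0.45
        assert est.beta == 20  # mean(laid + residual) over the 6 females
        assert est.X == pytest.approx((6 + 5 + 6) / (20 + 18 + 20))
        assert est.s2 == 0.0
        assert 0 < est.mu2 < 1
        assert est.n_survival == 8
        model = est.to_model_params()
        assert model.host2.a == pytest.approx(est.a_rel)
        assert model.host1.K == 1000.0  # un-assayed quantities from the base config

    def test_flat_config_round_trips_to_model_params(self):
        from eggsink.params import ModelParams

        ovi = oviposition_table([22, 22], [10, 10])
        dev = pd.concat(
            [
                development_table([20, 18], [12, 11], [6, 5]),
                development_table(
                    [0, 0], [0, 0], [0, 0],
                    species="unsuitable", treatment="no-choice-unsuitable",
                ),
            ],
            ignore_index=True,
        )
        surv = survival_table([12, 12], [30, 31])
        cfg = estimate_all(ovi, dev, surv).to_flat_config()
        params = ModelParams.from_flat_dict(cfg)
        assert params.host2.a == cfg["a2"]
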