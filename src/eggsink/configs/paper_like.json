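{
  "allocation": "quota",
  "attack_ratio": 2.2,
  "egg_load_intercept": -24.68,
  "egg_load_r2": 0.39,
  "egg_load_slope": 164.79,
  "emergence_rate": 0.6,
  "fecundity_target_control": 30.7,
  "fecundity_target_parasitized": 12.2,
  "female_share": 0.48,
  "lay_fraction_development": 0.95,
  "lay_fraction_oviposition": 0.625,
  "longevity_mean_control": 28.0,
  "longevity_mean_parasitized": 20.0,
  "mummification_suitable": 0.95,
  "mummification_unsuitable": 0.0,
  "n_control": 33,
  "n_parasitized": 37,
  "n_replicates": {
    "choice-high": 25,
    "choice-low": 25,
    "no-choice-suitable": 25,
    "no-choice-unsuitable": 25
  },
  "overdispersion_k": 5.0,
  "prereproductive_days": 7,
  "seed": 0,
  "supply_cap": 20,
  "supply_dist": "binomial",
  "supply_mean": 16.0,
  "tibia_mean_mm": 0.25,
  "tibia_sd_mm": 0.02
}
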