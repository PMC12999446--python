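# Swiss pork production, reference year 2023.
#
# Scenario parameters are industry aggregates (UFA / AGRIDEA 2023 levels);
# percentages are stored as fractions, weights in kg liveweight, durations
# in days, money in CHF.  The USD rate under meta is documentation only and
# is never applied in computation.
#
# The price book is reconstructed: each unit price is solved from the
# published per-sow / per-pig revenue and cost aggregates by a min-max
# residual fit across the three scenarios (see swine_ahle.fixtures
# .solve_price_book, the executable oracle).  Entries marked "printed"
# are taken directly from published lines; "solved" entries reproduce
# every aggregate line within +/-1 CHF (+/-1.5 for reared-piglet revenue).
meta:
  name: swiss_2023
  year: 2023
  currency: CHF
  usd_per_chf: 1.25  # metadata only
population:
  breeding_sows: 100878
  slaughter_pigs: 2433981
simulation:
  iterations: 10000
  seed: 20230
  percentiles: [5.0, 95.0]
sensitivity:
  increments: 7
  iterations_per_increment: 1000
  parameters: []  # empty = the default 13-parameter set
price_book:
  reared_piglet_price: 116.96272     # solved; CHF per reared piglet sold at 26 kg
  cull_sow_price: 172.60274          # solved; CHF per culled sow (net of culling losses)
  gilt_price: 798.98734              # solved; CHF per replacement gilt
  insemination_price: 12.55227       # solved; CHF per service (failed services are paid)
  sow_gestation_feed_rate: 1.70308   # solved; CHF per non-lactating sow-day
  sow_lactation_feed_rate: 4.75034   # solved; CHF per lactating sow-day
  starter_feed_per_weaned: 1.53541   # solved; CHF per weaned piglet
  rearing_feed_price: 0.77936        # solved; CHF per kg rearing feed (FCR-based)
  gilt_feed_per_replacement: 389.58904  # solved; CHF gilt rearing feed per replacement
  vet_fixed_per_farm: 209.18919      # solved; herd-health visit, CHF per farm-year
  vet_per_sow:                       # solved; CHF per sow-year on top of the visit
    Average: 115.60541
    Top10: 136.60541
  vet_per_sow_ideal: 39.0            # printed; castration + iron injections only
  ear_tag_price: 0.34752             # solved; CHF per weaned piglet
  breeding_misc_fixed: 427.0         # printed; organizational 11 + cleaning 13 + transport 201
                                     #   + energy 50 + water 6 + straw 144 + label 2
  slaughter_pig_revenue: 320.0       # printed; CHF per slaughter pig, all scenarios
  fattening_piglet_base_price: 122.0518   # solved; purchase price at the base weight
  fattening_piglet_base_weight: 27.1
  fattening_piglet_price_per_kg_over_base: 5.15667  # solved from the Top10 start weight
  fattening_feed_price: 0.588852     # solved; CHF per kg fattening feed
  fattening_vet_per_pig:             # printed
    Average: 0.5
    Top10: 0.5
    Ideal: 0.0
  fattening_misc_per_pig: 41.0       # printed; sum of the miscellaneous lines
scenarios:
  Average:
    name: Average
    breeding:
      gestation_length: 115
      lactation_length: 31.6
      weaning_to_oestrus: 22
      piglet_weaning_weight: 8
      reared_sale_weight: 26
      rearing_duration: 42
      rearing_adg: {kind: fixed, value: 0.43, principle: F_calculated}
      rearing_fcr: 1.70
      sow_replacement_rate: 0.37
      litters_per_sow_year: 2.17
      return_to_oestrus_rate: 0.111
      piglets_weaned_per_litter: 11.7
      piglets_weaned_per_sow_year: 25.3
      piglets_born_alive_per_litter: 13.0
      preweaning_mortality: 0.105
      rearing_mortality: 0.02
      farrowing_rate: 0.81
      sow_liveweight: 200
    fattening:
      start_weight: 27.1
      slaughter_weight: 115.9
      fattening_duration: 97
      mortality: 0.0153
      fcr: 2.62
      adg: 917
      service_period: 16
  Top10:
    name: Top10
    breeding:
      gestation_length: 115
      lactation_length: 31.6
      weaning_to_oestrus: 11
      piglet_weaning_weight: 8
      reared_sale_weight: 26
      rearing_duration: 35
      rearing_adg: {kind: fixed, value: 0.51, principle: F_calculated}
      rearing_fcr: 1.50
      sow_replacement_rate: 0.32
      litters_per_sow_year: 2.31
      return_to_oestrus_rate: 0.038
      piglets_weaned_per_litter: 13.2
      piglets_weaned_per_sow_year: 30.6
      piglets_born_alive_per_litter: 14.3
      preweaning_mortality: 0.069
      rearing_mortality: 0.015
      farrowing_rate: 0.91
      sow_liveweight: 200
    fattening:
      start_weight: 27.7
      slaughter_weight: 116.8
      fattening_duration: 93
      mortality: 0.0146
      fcr: 2.35
      adg: 961
      service_period: 16
  Ideal:
    name: Ideal
    breeding:
      gestation_length: 115
      lactation_length: 31.6
      weaning_to_oestrus: 7
      piglet_weaning_weight: 8
      reared_sale_weight: 26
      rearing_duration: 32
      rearing_adg: {pert: [0.54, 0.57, 0.59], principle: C_pert}
      rearing_fcr: {pert: [1.28, 1.35, 1.43], principle: C_pert}
      sow_replacement_rate: {pert: [0.27, 0.29, 0.30], principle: C_pert}
      litters_per_sow_year: {pert: [2.31, 2.34, 2.37], principle: C_pert}
      return_to_oestrus_rate: 0.0
      piglets_weaned_per_litter: 17.6
      piglets_weaned_per_sow_year: 41.2
      piglets_born_alive_per_litter: {pert: [16.8, 17.6, 18.4], principle: C_pert}
      preweaning_mortality: 0.0
      rearing_mortality: 0.0
      farrowing_rate: 1.0
      sow_liveweight: 200
    fattening:
      start_weight: 27.1
      slaughter_weight: 115.9
      fattening_duration: {pert: [79, 83, 88], principle: C_pert}
      mortality: 0.0
      fcr: {pert: [2.00, 2.12, 2.23], principle: C_pert}
      adg: 1064
      service_period: 16
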