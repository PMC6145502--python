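# Desk-scale three-population analogue of the out-of-Africa history used by
# tests, fixtures and demos. It preserves the qualitative structure --
# African population, bottlenecked out-of-Africa deme splitting into two
# growing non-African populations with migration -- at population sizes and
# time depths small enough for forward simulation in seconds. Mutation and
# recombination rates are inflated to keep per-window polymorphism counts
# realistic (theta/bp ~ 1e-3) at the small sizes.
name: toy_ooa
generation_time: 25.0
mutation_rate: 1.0e-6
recombination_rate: 1.0e-6
populations:
  - {name: AFR, initial_size: 400}
  - {name: EUR, initial_size: 150, growth_rate: 0.004}
  - {name: ASN, initial_size: 120, growth_rate: 0.005}
migration:
  - [AFR, EUR, 2.0e-4]
  - [AFR, ASN, 1.0e-4]
  - [EUR, ASN, 4.0e-4]
events:
  - {type: split, time: 250, derived: ASN, ancestral: EUR}
  - {type: size_change, time: 250, population: EUR, size: 80, growth_rate: 0.0}
  - {type: migration_change, time: 250, rates: [[AFR, EUR, 1.0e-3]]}
  - {type: split, time: 600, derived: EUR, ancestral: AFR}
  - {type: size_change, time: 1600, population: AFR, size: 300}
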