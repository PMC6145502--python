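# Three-population out-of-Africa demographic model, maximum-likelihood
# parameters of Gravel et al. (2011, PNAS 108:11983), 1000G low-coverage fit.
# Times are generations before present at 25 years per generation.
#
# Field-by-field provenance (Gravel et al. 2011, Table 2):
#   N_A   (ancestral)            7310     -> size_change at 5920 gen (148 kya)
#   N_AF  (African)              14474    -> AFR initial_size
#   T_AF  (African expansion)    148 kya  -> 5920 gen
#   T_B   (out-of-Africa split)  51 kya   -> 2040 gen; N_B = 1861
#   T_EU-AS (Eurasian split)     23 kya   -> 920 gen
#   N_EU0 1032, r_EU 0.38%/gen; N_AS0 554, r_AS 0.48%/gen
#   m_AF-B 15e-5, m_AF-EU 2.5e-5, m_AF-AS 0.78e-5, m_EU-AS 3.11e-5
#   mu = 2.36e-8 per bp per generation
# The Eurasian bottleneck population B is represented by relabelling EUR
# between the two split times. Recombination defaults to the HapMap II
# genome average.
name: gravel_2011
generation_time: 25.0
mutation_rate: 2.36e-8
recombination_rate: 1.3e-8
# initial_size is the present-day size; the exponential growth rates place
# EUR at 1032 and ASN at 554 diploids at the 920-generation Eurasian split
# (N_EU0 / N_AS0 of the source fit).
populations:
  - {name: AFR, initial_size: 14474}
  - {name: EUR, initial_size: 34039, growth_rate: 0.0038}
  - {name: ASN, initial_size: 45852, growth_rate: 0.0048}
migration:
  - [AFR, EUR, 2.5e-5]
  - [AFR, ASN, 0.78e-5]
  - [EUR, ASN, 3.11e-5]
events:
  # Eurasian (EUR/ASN) split; EUR then stands for the bottleneck deme B
  - {type: split, time: 920, derived: ASN, ancestral: EUR}
  - {type: size_change, time: 920, population: EUR, size: 1861, growth_rate: 0.0}
  - {type: migration_change, time: 920, rates: [[AFR, EUR, 15.0e-5]]}
  # out-of-Africa split
  - {type: split, time: 2040, derived: EUR, ancestral: AFR}
  # African expansion: ancestral size before 148 kya
  - {type: size_change, time: 5920, population: AFR, size: 7310}
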