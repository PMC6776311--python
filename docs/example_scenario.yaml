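# Example scenario for `scatniche simulate`.
#
# Two sections, both optional:
#   diet:     -> synthetic scat collections (one entry per river-year group)
#   isotopes: -> synthetic per-scat delta values (one entry per group)
#
# Diet entries:
#   river, year          group labels
#   n_scats              scats to generate (>= 1)
#   items_per_scat_mean  mean prey items per scat; items are drawn as
#                        1 + Poisson(mean - 1), capped at the taxon count
#   proportions          taxon -> share of the diet (must sum to 1);
#                        within a scat taxa are drawn without replacement
#
# Isotope entries:
#   n                    samples to generate
#   d15N / d13C          mean and variance (permil) of the group's normals

diet:
  - river: Pasion
    year: 2015
    n_scats: 40
    items_per_scat_mean: 1.8
    proportions:
      Pterygoplichthys spp: 0.49
      Vieja bifasciata: 0.08
      Oreochromis aureus: 0.08
      Mayaheros urophtalmus: 0.07
      Parachromis friedrichsthalii: 0.07
      Cribroheros robertsoni: 0.06
      Thorichthys meeki: 0.05
      Poecilia mexicana: 0.05
      Catfish: 0.05

isotopes:
  - river: Pasion
    year: 2015
    n: 34
    d15N: {mean: 10.62, variance: 1.80}
    d13C: {mean: -28.0, variance: 6.49}
  - river: Pasion
    year: 2010
    n: 36
    d15N: {mean: 12.50, variance: 2.45}
    d13C: {mean: -27.5, variance: 3.65}
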