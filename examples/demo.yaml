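# Desk-scale demo configuration: ~2,000 events, runs in about a minute.
# Raise generator.n_cities / generator.years (and classifier.n_trees)
# for study-scale corpora.
generator:
  n_cities: 24
  years: 22
mechanism:
  target_prevalence: 0.05
classifier:
  n_trees: 60
importance_repeats: 5
seed: 3
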