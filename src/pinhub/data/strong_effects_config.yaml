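# "Strong effects" study conditions for the synthetic hub-role dataset and
# the reference experiment run against it.  These are the package defaults,
# written out so the conditions behind the synthetic benchmarks are explicit.
synthetic:
  n_proteins: 2000
  exponent: 2.5          # scale-free degree-law exponent
  hub_degree: 9          # degree >= 9 ("more than eight") -> hub
  nonhub_degree: 3       # degree < 3 -> non-hub
  pcc_threshold: 0.5     # avgPCC split of hubs into party (>=) / date (<)
  class_mix: [0.814, 0.098, 0.033, 0.055]   # NH / IC / PH / DH frequencies
  effect_size: 1.0       # 0 = all classes identical; 1 = default strong regime
  length_median: 450.0
  length_sigma: 0.45
  n_domain_vocab: 40
  composition_concentration: 100.0
experiment:
  train_fraction: 0.70
  folds: 5
  classifier: gauss
  min_risk: true
  n_components: 3
  screen_fraction: 0.5
  fusion: true
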