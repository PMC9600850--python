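{
  "mmv1": {
    "mode": "mmv1",
    "lambda": 0.020000000000001794,
    "intercept": 5.44895763506326,
    "coefficients": {
      "cub_he": -7.104333599955275
    },
    "with_temperature": false,
    "training_metadata": {
      "n": 300,
      "r_squared": 0.38581462304994596,
      "response": "doubling_time_h",
      "source": "SYNTHETIC",
      "note": "fitted on the cubgrowth synthetic genome generator; replace with a real training table for scientific use",
      "generator_seed": 12060,
      "n_genomes": 300,
      "n_clusters": 6
    }
  },
  "mmbc": {
    "mode": "mmbc",
    "lambda": 0.07000000000000206,
    "intercept": 5.068398149496442,
    "coefficients": {
      "normalized_cub": 7.26109092842745,
      "gc_deviation": -12.642133374509111
    },
    "with_temperature": false,
    "training_metadata": {
      "n": 300,
      "r_squared": 0.49571523630717096,
      "response": "doubling_time_h",
      "source": "SYNTHETIC",
      "note": "fitted on the cubgrowth synthetic genome generator; replace with a real training table for scientific use",
      "generator_seed": 12060,
      "n_genomes": 300,
      "n_clusters": 6
    }
  }
}
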