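{
  "mmv1": {
    "mode": "mmv1",
    "lambda": -0.0899999999999983,
    "intercept": 5.450787130076982,
    "coefficients": {
      "cub_he": -6.651827187584907,
      "ogt": -0.015834333129951163
    },
    "with_temperature": true,
    "training_metadata": {
      "n": 300,
      "r_squared": 0.4757526553646183,
      "response": "doubling_time_h",
      "source": "SYNTHETIC",
      "note": "fitted on the cubgrowth synthetic genome generator; replace with a real training table for scientific use",
      "generator_seed": 13060,
      "n_genomes": 300,
      "n_clusters": 6
    }
  },
  "mmbc": {
    "mode": "mmbc",
    "lambda": -0.0799999999999983,
    "intercept": 4.794770980992785,
    "coefficients": {
      "normalized_cub": 6.6220156178142915,
      "gc_deviation": -10.33182080663962,
      "ogt": -0.016052857274058585
    },
    "with_temperature": true,
    "training_metadata": {
      "n": 300,
      "r_squared": 0.5180262278024965,
      "response": "doubling_time_h",
      "source": "SYNTHETIC",
      "note": "fitted on the cubgrowth synthetic genome generator; replace with a real training table for scientific use",
      "generator_seed": 13060,
      "n_genomes": 300,
      "n_clusters": 6
    }
  }
}
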