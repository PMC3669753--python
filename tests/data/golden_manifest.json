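{
  "counts": {
    "largest_module_size": 30,
    "n_baitprey_edges": 147,
    "n_baitprey_nodes": 50,
    "n_baits": 13,
    "n_de_down_loose": 68,
    "n_de_down_strict": 51,
    "n_de_up_loose": 63,
    "n_de_up_strict": 51,
    "n_genes": 1000,
    "n_modules": 2,
    "n_network_edges": 625,
    "n_network_nodes": 50,
    "n_preys": 89,
    "n_significant_terms": 1
  },
  "seed": 20130603
}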