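{
  "qtl": {
    "name": "qNFFB-D3-1",
    "chrom": "D3",
    "start": 17130008,
    "end": 41839226
  },
  "bsa_regions": [
    {"chrom": "D3", "start": 41779195, "end": 41836120},
    {"chrom": "D3", "start": 41836768, "end": 41872287}
  ],
  "printed": {
    "at_n_markers": 5595,
    "at_length_cM": 2117.74,
    "dt_n_markers": 5893,
    "dt_length_cM": 2084.38,
    "total_n_markers": 11488,
    "total_length_cM": 4202.12,
    "d3_avg_interval_cM": 2.03,
    "qtl_length_Mb": 24.7,
    "common_regions_total_Kb": 92.4
  }
}
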