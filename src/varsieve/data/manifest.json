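{
  "cohort_candidate_variants.tsv": "c2747ae2a9e40a235949fcf0acf99fc0dfaf5a70efa214aa0fec2a688086e00e",
  "high_risk_conservation.tsv": "34bcef91b5eada61c3bdf8c38734c42769914105cce7581730b1f4875a05fe0d",
  "high_risk_stability_structure.tsv": "f37b406292bc79a1b4417cacf50741f319fca68e70409bd2af7c1844d218cd27",
  "model_benchmark_confusion.tsv": "b57bda84d84c449b13e8883e56576dd4f10bea1f8d17f27859be8dda219a2ed8",
  "shortlist_annotations.tsv": "0e6ec90af3dc59c5d7029b595f89cf77b139fbdc7412680b7bb0281ead3c79be"
}
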