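{
  "title": "tfrctx summary report",
  "type": "object",
  "required": [
    "n_tfr_total",
    "per_replicon",
    "group_counts",
    "group_fractions",
    "mixed_count",
    "separation_histogram",
    "bin_width",
    "threshold_bp",
    "n_predicted",
    "category_counts",
    "ec_counts",
    "category_frac_within",
    "regional_densities"
  ],
  "properties": {
    "n_tfr_total": {"type": "integer"},
    "per_replicon": {"type": "object"},
    "group_counts": {"type": "object"},
    "group_fractions": {"type": "object"},
    "mixed_count": {"type": "integer"},
    "separation_histogram": {"type": "object"},
    "bin_width": {"type": "integer"},
    "threshold_bp": {"type": "integer"},
    "n_predicted": {"type": "integer"},
    "category_counts": {"type": "object"},
    "ec_counts": {"type": "object"},
    "category_frac_within": {"type": "object"},
    "regional_densities": {"type": "array"}
  }
}
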