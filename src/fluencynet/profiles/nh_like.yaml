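# Larger-lexicon, longer-retrieval group profile (normal-hearing-like).
# 27 subjects drawing ~18 words each from a 200-word lexicon of 12
# subcategories; calibrated so a group draw names ~132 distinct words.
label: nh_like
spec:
  n_subjects: 27
  subcategory_sizes: [30, 26, 24, 20, 18, 16, 14, 14, 12, 10, 8, 8]
  zipf_exponent: 1.0
  knowledge_decay: 1.1
  retrieval_mean: 18.0
  retrieval_sd: 4.0
  p_switch: 0.35
  p_know: 0.95
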