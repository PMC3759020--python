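# Smaller-coverage, shorter-retrieval group profile (cochlear-implant-like).
# Same lexicon as nh_like but lower word knowledge and shorter retrieval;
# calibrated so a 27-subject draw names ~106 distinct words.
label: ci_like
spec:
  n_subjects: 27
  subcategory_sizes: [30, 26, 24, 20, 18, 16, 14, 14, 12, 10, 8, 8]
  zipf_exponent: 1.0
  knowledge_decay: 1.3
  retrieval_mean: 13.0
  retrieval_sd: 3.5
  p_switch: 0.35
  p_know: 0.85
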