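cohort_id	n_relevant_freq	n_relevant_tfidf	n_relevant_union	n_relevant_intersection	ap_freq	ap_tfidf	n_reference	n_reference_matched	coverage
cohort	10	10	10	10	0.980909	1.000000	10	10	1.000000
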