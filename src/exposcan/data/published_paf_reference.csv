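# Published per-domain PAF table: unweighted PAF, PCA communality and
# communality-weighted PAF (percent) for the five scoreable domains under
# the conservative (1) and optimistic (2) counterfactual models, plus the
# published overall weighted PAF per model.
domain,model,unweighted_paf,communality,weighted_paf
socioeconomic_status,1,1.47,20.45,0.66
medical_history,1,8.15,32.41,4.64
psychosocial,1,11.02,39.50,6.93
physical_measures,1,9.26,23.39,4.48
lifestyle,1,9.27,18.27,3.96
overall,1,,,20.67
socioeconomic_status,2,6.30,14.20,2.37
medical_history,2,12.57,22.44,5.96
psychosocial,2,15.03,38.62,9.34
physical_measures,2,18.14,34.26,10.62
lifestyle,2,12.60,19.59,5.58
overall,2,,,33.87
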