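superseding,superseded,vocabulary
diabetes_complicated,diabetes_uncomplicated,charlson
liver_moderate_severe,liver_mild,charlson
metastatic_tumor,malignancy,charlson
diabetes_complicated,diabetes_uncomplicated,elixhauser
hypertension_complicated,hypertension_uncomplicated,elixhauser
metastatic_cancer,solid_tumor,elixhauser
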