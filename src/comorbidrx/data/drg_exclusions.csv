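mrdx_category,condition_id
intracranial_hemorrhage,cerebrovascular
intracranial_hemorrhage,paralysis
ischemic_infarct,cerebrovascular
ischemic_infarct,paralysis
pneumonia,chronic_pulmonary
aspiration_pneumonia,chronic_pulmonary
copd,chronic_pulmonary
acute_myocardial_infarction,myocardial_infarction
coronary_atherosclerosis,myocardial_infarction
congestive_heart_failure,congestive_heart_failure
chronic_renal_failure,renal_disease
chronic_renal_failure,renal_failure
nonalcoholic_liver_disease,liver_mild
nonalcoholic_liver_disease,liver_moderate_severe
nonalcoholic_liver_disease,liver_disease
alcoholic_liver_disease,liver_mild
alcoholic_liver_disease,liver_moderate_severe
alcoholic_liver_disease,liver_disease
alcoholic_liver_disease,alcohol_abuse
intracranial_injury,paralysis
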