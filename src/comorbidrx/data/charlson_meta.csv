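condition_id,weight,chronic
myocardial_infarction,1,0
congestive_heart_failure,1,1
peripheral_vascular,1,1
cerebrovascular,1,1
dementia,1,1
chronic_pulmonary,1,1
rheumatic_disease,1,1
peptic_ulcer,1,1
liver_mild,1,1
diabetes_uncomplicated,1,1
diabetes_complicated,2,1
hemiplegia_paraplegia,2,1
renal_disease,2,1
malignancy,2,1
liver_moderate_severe,3,1
metastatic_tumor,6,1
hiv_aids,6,1
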