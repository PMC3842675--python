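# Synthetic drug->condition fixture map. The study's curated national
# formulary lists are not public; these rows are illustrative generics chosen
# so that every inferable condition has one eligible oral single-indication
# drug and every eligibility-exclusion criterion is exercised.
drug_id,condition_id,vocabulary,route,is_antineoplastic,multi_indication,mild_condition_only
digoxin,congestive_heart_failure,charlson,oral,0,0,0
cilostazol,peripheral_vascular,charlson,oral,0,0,0
nicergoline,cerebrovascular,charlson,oral,0,0,0
donepezil,dementia,charlson,oral,0,0,0
tiotropium,chronic_pulmonary,charlson,oral,0,0,0
hydroxychloroquine,rheumatic_disease,charlson,oral,0,0,0
sevelamer,renal_disease,charlson,oral,0,0,0
zidovudine,hiv_aids,charlson,oral,0,0,0
digoxin,congestive_heart_failure,elixhauser,oral,0,0,0
amiodarone,cardiac_arrhythmia,elixhauser,oral,0,0,0
cilostazol,peripheral_vascular,elixhauser,oral,0,0,0
levodopa,other_neurological,elixhauser,oral,0,0,0
tiotropium,chronic_pulmonary,elixhauser,oral,0,0,0
levothyroxine,hypothyroidism,elixhauser,oral,0,0,0
sevelamer,renal_failure,elixhauser,oral,0,0,0
lactulose,liver_disease,elixhauser,oral,0,0,0
zidovudine,hiv_aids,elixhauser,oral,0,0,0
hydroxychloroquine,rheumatoid_arthritis,elixhauser,oral,0,0,0
megestrol,weight_loss,elixhauser,oral,0,0,0
ferrous_sulfate,deficiency_anemia,elixhauser,oral,0,0,0
clozapine,psychoses,elixhauser,oral,0,0,0
fluoxetine,depression,elixhauser,oral,0,0,0
paroxetine,depression,elixhauser,oral,0,1,0
amlodipine,hypertension_uncomplicated,elixhauser,oral,0,0,0
metformin,diabetes_uncomplicated,charlson,oral,0,0,0
metformin,diabetes_uncomplicated,elixhauser,oral,0,0,0
methotrexate,rheumatic_disease,charlson,oral,1,0,0
heparin,coagulopathy,elixhauser,parenteral,0,0,0
clotrimazole_topical,liver_mild,charlson,topical,0,0,1
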