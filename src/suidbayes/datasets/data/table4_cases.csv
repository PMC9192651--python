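case_id,diagnosis,age_months,age_band,sex,gestational_age,birth_weight,death_during_sleep,co_sleeping,sleep_position,maternal_age,siblings,suid_history,breastfeeding,passive_smoking,alcohol_influence,vaccination,maltreatment,infection_symptoms
case-1,internal,6,3-6,female,>=37,<2500,yes,no,prone,20-34,1,no,yes,yes,no,yes,no,no
case-2,SIDS,6,3-6,female,>=37,>=2500,yes,no,supine,>=35,0,no,yes,no,no,yes,no,no
case-3,SIDS,5,3-6,male,>=37,>=2500,yes,no,prone,20-34,0,no,yes,no,no,no,no,no
case-4,internal,11,7-11,female,>=37,>=2500,yes,yes,other,20-34,>=2,no,yes,no,no,no,yes,no
case-5,SIDS,0,0-2,male,>=37,>=2500,yes,yes,prone,20-34,1,no,no,yes,no,no,no,no
case-6,SIDS,6,3-6,female,>=37,>=2500,yes,yes,supine,20-34,1,no,no,no,no,no,no,yes
case-7,SIDS,8,7-11,female,>=37,>=2500,yes,no,prone,20-34,0,no,no,no,no,no,no,no
case-8,SIDS,0,0-2,female,>=37,>=2500,yes,yes,supine,20-34,>=2,no,yes,yes,no,no,yes,no
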