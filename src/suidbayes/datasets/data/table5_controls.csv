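factor,level,stratum,count,proportion,source_note
age_band,0-2,all,,0.25,uniform by month of age (3 of 12 months)
age_band,3-6,all,,0.3333333333,uniform by month of age (4 of 12 months)
age_band,7-11,all,,0.4166666667,uniform by month of age (5 of 12 months)
sex,male,all,6865626,,national vital statistics 2006-2018
sex,female,all,6518337,,national vital statistics 2006-2018
gestational_age,<37,all,762547,,national vital statistics 2006-2018 (4083 unrecorded excluded)
gestational_age,>=37,all,12617333,,national vital statistics 2006-2018 (4083 unrecorded excluded)
birth_weight,<2500,all,1276948,,national vital statistics 2006-2018 (2348 unrecorded excluded)
birth_weight,>=2500,all,12104667,,national vital statistics 2006-2018 (2348 unrecorded excluded)
co_sleeping,yes,0-2,43,,published infant sleep-environment survey
co_sleeping,no,0-2,98,,published infant sleep-environment survey
co_sleeping,yes,3-6,74,,published infant sleep-environment survey
co_sleeping,no,3-6,65,,published infant sleep-environment survey
co_sleeping,yes,7-11,85,,published infant sleep-environment survey
co_sleeping,no,7-11,73,,published infant sleep-environment survey
sleep_position,prone,all,422,,published sleeping-position survey
sleep_position,not_prone,all,1816,,published sleeping-position survey
breastfeeding,yes,0-2,3555,,national nutrition survey on preschool children 2015
breastfeeding,no,0-2,148,,national nutrition survey on preschool children 2015
breastfeeding,yes,3-6,4011,,national nutrition survey on preschool children 2015
breastfeeding,no,3-6,700,,national nutrition survey on preschool children 2015
breastfeeding,yes,7-11,,0.811,national nutrition survey (proportions only published)
breastfeeding,no,7-11,,0.189,national nutrition survey (proportions only published)
passive_smoking,yes,all,,0.331,adult tobacco-consumption prevalence 2018 (proportions only)
passive_smoking,no,all,,0.669,adult tobacco-consumption prevalence 2018 (proportions only)
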