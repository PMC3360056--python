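category,label,unit,price_eur_2007,group
gp_office_visit,Visit to GP,per visit,21.36,primary_care
gp_home_visit,Visit from GP,per visit,42.73,primary_care
gp_phone,GP contact by telephone,per contact,10.66,primary_care
physiotherapy,Physiotherapy,per visit,22.40,primary_care
ergotherapy,Ergotherapy,per visit,53.03,primary_care
psychologist,Psychologist,per visit,81.02,primary_care
psychiatrist,Psychiatrist,per visit,80.38,primary_care
social_psychiatric_nurse,Social psychiatric nurse,per visit,80.38,primary_care
geriatrician,Geriatrician,per visit,177.69,secondary_care
other_specialist,Other specialist,per visit,59.23,secondary_care
hospital_day_care,Hospital admission day care,per day,242.15,secondary_care
hospital_overnight,Hospital overnight stay,per day,353.35,secondary_care
informal_care,Informal care,per hour,8.78,informal_care
medication,Medication (pre-costed),per euro,1.00,medication
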