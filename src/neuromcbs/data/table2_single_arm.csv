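record_id,study,design,primary_endpoint,n_subjects,single_arm_pfs_months,orr_pct,dor_months,dor_statistic,docb_months,response_criteria,toxicity_ge30pct_grade34,qol_assessed,qol_improved,entity,subgroup_label,note,expected_form,expected_esmo_score,expected_neuro_score,expected_status,expected_reason
roar_hgg,ROAR,single_arm,ORR,45,4.5,31,13.6,mean,,RANO,yes,unknown,unknown,high-grade glioma,High-grade glioma cohort,basket-trial cohort scored as a separate single-arm study,form3,2,2,scored,
roar_lgg,ROAR,single_arm,ORR,13,14.0,69,27.5,mean,,RANO,no,unknown,unknown,low-grade glioma,Low-grade glioma cohort,basket-trial cohort scored as a separate single-arm study,form3,3,3,scored,
alliance_071601,Alliance 071601,single_arm,ORR,16,,94,,unspecified,,CR+PR,yes,unknown,unknown,papillary craniopharyngioma,,,form3,2,2,scored,
everolimus_sega,NCT00411619/EXIST-1,single_arm,safety,28,,75,,unspecified,,change in tumor volume within 6 months,yes,yes,yes,subependymal giant-cell astrocytoma,,,form3,3,3,scored,
selumetinib_nf1,NCT01362803,single_arm,ORR,50,,68,not reached,unspecified,,volumetric MRI,no,yes,yes,plexiform neurofibroma,,,form3,4,4,scored,
pbtc_029,PBTC-029,single_arm,ORR,25,,24,,unspecified,,CR+PR sustained >= 8 weeks,no,unknown,unknown,optic pathway/hypothalamic low-grade glioma,,DoR not reported; response criteria amended during study,form3,n/a,n/a,not_assessable,duration_of_response_missing
onc201_dmg,Arrillaga-Romany et al.,single_arm,ORR,50,,20,11.2,mean,,RANO,no,unknown,unknown,diffuse midline glioma,,post hoc pooled efficacy analysis of single-arm studies,form3,3,3,scored,
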