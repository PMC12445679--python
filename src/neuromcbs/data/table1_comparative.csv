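record_id,study,subgroup_label,design,primary_endpoint,n_subjects,superiority_met,noninferiority_met,pfs_gain,pfs_gain_unit,pfs_hr,os_gain,os_gain_unit,os_hr,external_os_control_median_months,qol_assessed,qol_improved,note,expected_form,expected_esmo_score,expected_status,expected_reason,expected_asco_reason
eortc26981,EORTC 26981-22981/NCIC CE3,,comparative_superiority,OS,573,yes,unknown,1.9,months,0.63 (0.53–0.75),2.5,months,0·63 (0·53–0·75),12.1,unknown,unknown,band-dependent: grade needs the control-arm median OS (external value),form2a,2,scored,,
ef14,EF-14,,comparative_superiority,PFS,695,yes,unknown,2.7,months,0.63 (0.52–0.76),4.9,months,0.63 (0.53–0.76),16.0,unknown,unknown,promoted to Form 2a (OS benefit demonstrated); band-dependent: control-arm median OS is external,form2a,3,scored,,
ceteg,CeTeG/NOA-09,,comparative_superiority,OS,144,yes,unknown,,,0.99 (0·68–1·46),16.5,months,0.6 (0.35–1.03),,unknown,unknown,,form2a,4,scored,,
noa08,NOA-08,,comparative_noninferiority,OS,373,no,yes,-1.4,months,1.15 (0.92–1.43),-1,months,1.09 (0.84–1.42),,unknown,unknown,non-inferiority design; toxicity reporting insufficient for Form 2c,form2c,n/a,not_assessable,insufficient_toxicity_data,noninferiority_design_unsupported
nordic_hfrt,Nordic Trial,HFRT arm,comparative_superiority,OS,98,no,unknown,,,,1.5,months,0.85 (0.64–1.12),,unknown,unknown,arm did not reach statistical superiority,form2a,n/a,not_assessable,no_statistical_significance,no_statistical_significance
nordic_tmz,Nordic Trial,TMZ arm,comparative_superiority,OS,93,yes,unknown,,,,2.3,months,0.70 (0.52–0.93),,unknown,unknown,only the TMZ arm reached statistical superiority,form2a,2,scored,,
perry,Short-course radiation plus Temozolomide in the elderly,,comparative_superiority,OS,562,yes,unknown,1.4,months,0.50 (0.41–0.60),1.7,months,0.67 (0.56–0.80),,unknown,unknown,mPFS gain printed without a unit; stored as months consistent with the column,form2a,2,scored,,
rtog9402_overall,RTOG9402,,comparative_superiority,OS,291,no,unknown,,,,-0.1,years,0.79 (0.60–1.04),,unknown,unknown,overall comparison not statistically significant,form2a,n/a,not_assessable,no_statistical_significance,no_statistical_significance
rtog9402_idh,RTOG9402,IDH mutant,comparative_superiority,OS,156,yes,unknown,,,,3.7,years,0.59 (0.40–0.86),,unknown,unknown,post hoc molecular subgroup,form2a,4,scored,,
rtog9402_codel,RTOG9402,1p19q co-del,comparative_superiority,OS,10,yes,unknown,,,,7.3,years,0.59 (0.37–0.95),,unknown,unknown,printed n=10 reproduced as printed despite apparent inconsistency,form2a,4,scored,,
rtog9402_idh_codel,RTOG9402,IDH mutant and 1p19q co-del,comparative_superiority,OS,88,yes,unknown,,,,7.9,years,0.49 (0.28–0.85),,unknown,unknown,post hoc molecular subgroup,form2a,4,scored,,
rtog9402_idh_noncodel,RTOG9402,"IDH mutant, not 1p19q co-del",comparative_superiority,OS,66,yes,unknown,,,,2.2,years,0.56 (0.32–0.99),,unknown,unknown,post hoc molecular subgroup,form2a,4,scored,,
rtog9402_neither,RTOG9402,"Not IDH-mutant, not 1p19q co-del",comparative_superiority,OS,44,no,unknown,,,,-0.3,years,0.99 (0.53–1.86),,unknown,unknown,subgroup not statistically significant,form2a,n/a,not_assessable,no_statistical_significance,no_statistical_significance
eortc26951,EORTC 26951,,comparative_superiority,OS,368,yes,unknown,11.1,months,0.66 (0.52–0.83),11.7,months,0.75 (0.60–0.95),,unknown,unknown,,form2a,4,scored,,
rtog9802,RTOG 9802,,comparative_superiority,OS,251,yes,unknown,6.4,years,0.5 (0.36–0.68),5.5,years,0.59 (0.42–0.83),,unknown,unknown,gains printed in years; normalised to months on load,form2a,4,scored,,
indigo,INDIGO,,comparative_superiority,PFS,331,yes,unknown,16.6,months,0.39 (0.27–0.56),,,,,yes,yes,editorial assumption: upgrade credit (QoL) encoded to reproduce the printed final 4,form2b,4,scored,,
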