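review_id,intervention,review_type,is_nma,primary_outcome,polarity,n_included,n_non_rct,n_no_concern,k_original,measure,point_original,ci_low_original,ci_high_original,k_sensitivity,sens_estimable,point_sensitivity,ci_low_sensitivity,ci_high_sensitivity,k_original_rct_only,point_original_rct_only,ci_low_original_rct_only,ci_high_original_rct_only,notes
Popp-2021a,antibiotics,cochrane,False,all_cause_mortality,lower_is_benefit,11,0,6,4,RR,0.98,0.90,1.06,3,True,0.98,0.90,1.06,,,,,
Zhang-2021,antibiotics,non_cochrane,True,all_cause_mortality,lower_is_benefit,16,0,8,12,OR,0.94,0.62,1.52,8,False,,,,,,,,network meta-analysis; no sensitivity re-pooling
Flumignan-2022,anticoagulants,cochrane,False,all_cause_mortality,lower_is_benefit,4,0,1,4,RR,1.03,0.92,1.16,1,True,1.00,0.86,1.15,,,,,
Aamir Waheed-2022,anticoagulants,non_cochrane,False,all_cause_mortality,lower_is_benefit,12,9,1,9,OR,0.63,0.54,0.72,1,True,1.08,0.85,1.38,,,,,original pool mixed in 6 non-randomized studies
Mikolajewska-2021,colchicine,cochrane,False,all_cause_mortality,lower_is_benefit,4,0,1,2,RR,1.00,0.93,1.08,1,True,1.01,0.94,1.08,,,,,
Kow-2022,colchicine,non_cochrane,False,all_cause_mortality,lower_is_benefit,10,0,3,9,OR,0.76,0.53,1.07,3,True,1.01,0.93,1.10,,,,,
Piechotta-2021,convalescent_plasma,cochrane,False,all_cause_mortality,lower_is_benefit,12,0,5,7,RR,0.98,0.92,1.05,5,True,0.98,0.92,1.05,,,,,
Deng-2022,convalescent_plasma,non_cochrane,True,all_cause_mortality,lower_is_benefit,32,0,13,27,OR,0.93,0.84,1.03,11,False,,,,,,,,network meta-analysis; no sensitivity re-pooling
Singh-2021,hydroxychloroquine_or_chloroquine,cochrane,False,all_cause_mortality,lower_is_benefit,14,0,5,9,RR,1.09,0.99,1.19,4,True,1.09,0.99,1.19,,,,,
Siemieniuk-2020,hydroxychloroquine_or_chloroquine,non_cochrane,True,all_cause_mortality,lower_is_benefit,45,0,10,35,RR,1.09,0.93,1.27,8,False,,,,,,,,network meta-analysis; no sensitivity re-pooling
Griesel-2022,inhaled_corticosteroids,cochrane,False,all_cause_mortality,lower_is_benefit,3,0,2,3,RR,0.61,0.22,1.67,2,True,0.61,0.22,1.67,,,,,
Zhang-2021,inhaled_corticosteroids,non_cochrane,True,all_cause_mortality,lower_is_benefit,4,0,2,1,OR,0.95,0.63,1.69,1,True,0.95,0.63,1.69,,,,,single-trial network row; sensitivity identical
Davidson-2022,interleukin_1_blocking_agents,cochrane,False,clinical_improvement,higher_is_benefit,6,0,2,3,RR,1.08,0.97,1.20,2,True,1.12,1.03,1.21,,,,,
Naveed-2022,interleukin_1_blocking_agents,non_cochrane,False,all_cause_mortality,lower_is_benefit,4,1,1,16,RR,0.64,0.49,0.83,1,True,0.93,0.47,1.83,4,1.04,0.76,1.41,original pool mixed RCTs and non-randomized studies; RCT-only recalculation in alt columns
Ghosn-2021,interleukin_6_blocking_agents,cochrane,False,clinical_improvement,higher_is_benefit,10,0,2,7,RR,1.06,1.00,1.13,1,True,1.14,1.08,1.21,,,,,
Yu-2022,interleukin_6_blocking_agents,non_cochrane,False,all_cause_mortality,lower_is_benefit,17,0,4,16,RR,0.88,0.82,0.95,4,True,0.84,0.78,0.91,,,,,
Popp-2021b,ivermectin,cochrane,False,all_cause_mortality,lower_is_benefit,14,0,3,2,RR,0.60,0.14,2.51,0,False,,,,,,,,
Izcovich-2022,ivermectin,non_cochrane,False,all_cause_mortality,lower_is_benefit,29,0,4,12,RR,0.50,0.28,0.88,1,True,0.33,0.01,8.05,,,,,
Ansems-2021,remdesivir,cochrane,False,all_cause_mortality,lower_is_benefit,5,0,3,4,RR,0.93,0.81,1.06,3,True,0.90,0.75,1.08,,,,,
Lee-2022,remdesivir,non_cochrane,False,all_cause_mortality,lower_is_benefit,8,0,4,8,RR,0.92,0.78,1.08,4,True,0.91,0.71,1.15,,,,,
Kreuzberger-2021,sars_cov_2_neutralizing_mabs,cochrane,False,all_cause_mortality,lower_is_benefit,6,0,2,1,RR,0.94,0.87,1.02,1,True,0.94,0.87,1.02,,,,,
Deng-2022,sars_cov_2_neutralizing_mabs,non_cochrane,True,all_cause_mortality,lower_is_benefit,18,0,4,5,OR,0.86,0.73,1.02,2,False,,,,,,,,network meta-analysis; no sensitivity re-pooling
Wagner-2021,systemic_corticosteroids,cochrane,False,all_cause_mortality,lower_is_benefit,11,0,4,9,RR,0.89,0.80,1.00,4,True,0.90,0.84,0.97,,,,,
Siemieniuk-2020,systemic_corticosteroids,non_cochrane,True,all_cause_mortality,lower_is_benefit,14,0,4,11,RR,0.83,0.69,0.98,4,False,,,,,,,,network meta-analysis; no sensitivity re-pooling
Stroehlein-2021,vitamin_d,cochrane,False,all_cause_mortality,lower_is_benefit,3,0,0,2,RR,0.58,0.05,7.20,0,False,,,,,,,,
Hosseini-2022,vitamin_d,non_cochrane,False,covid_19_mortality,lower_is_benefit,9,1,0,4,RR,0.56,0.25,1.25,0,False,,,,,,,,RCT subgroup of a mixed pool
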