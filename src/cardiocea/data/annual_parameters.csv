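name,baseline,low,high,dist_family,shape_a,shape_b,units,role,source
init_low_pce,0.41,0.205,0.615,beta,8.66,12.46,fraction,probability,US multi-ancestry cohort study
init_moderate_pce,0.363,0.181,0.544,beta,9.45,16.58,fraction,probability,US multi-ancestry cohort study
init_high_pce,0.227,0.114,0.341,beta,11.61,39.53,fraction,probability,US multi-ancestry cohort study
enrollment,0.52,0.26,0.78,beta,6.86,6.33,fraction,probability,workplace program participation survey
risk_cad_high_pce,0.022,0.017,0.027,beta,76.39,3380.45,1/yr,probability,annualized 20% 10-year PCE risk
risk_cad_moderate_pce,0.013,0.005,0.022,beta,9.33,697.44,1/yr,probability,annualized 12.5% 10-year PCE risk
or_cad_high_prs,1.9,1.8,2,lognormal,0.64,0.05,ratio,relative_effect,top-quintile CAD-PRS association
hr_cad_diabetes,2,1.83,2.19,lognormal,0.57,0.22,ratio,relative_effect,cohort study
risk_cad_after_ischemic_stroke,0.017,0.014,0.019,beta,174.59,10095.92,1/yr,probability,cohort study
risk_ischemic_stroke,0.004,0.003,0.005,beta,95.65,23817.31,1/yr,probability,US incidence 800k*0.9/200M
risk_ischemic_stroke_after_cad,0.015,0.015,0.015,beta,60.528616,3974.712451,1/yr,probability,cohort study; no printed range
hr_ischemic_stroke_diabetes,2.27,1.95,2.65,lognormal,0.37,0.26,ratio,relative_effect,cohort study
risk_ischemic_stroke_post_hemorrhagic,0.057,0.048,0.068,beta,117.64,1946.26,1/yr,probability,cohort study
statin_hr_cad,0.56,0.4,0.78,lognormal,-0.58,0.09,ratio,relative_effect,"pravastatin trial, high CAD-PRS"
statin_hr_ischemic_stroke,0.77,0.63,0.94,lognormal,-0.26,0.08,ratio,relative_effect,statin trial meta-analysis
statin_adherence,0.5,0.4,0.6,beta,47.52,47.52,fraction,probability,assumption
risk_myopathy,0.0001,0.0001,0.0002,beta,2397.88,23976402.12,1/yr,probability,statin safety review
risk_statin_diabetes,0.0015,0.001,0.002,beta,847.59,564212.41,1/yr,probability,statin safety review
risk_statin_hemorrhagic_stroke,0.0002,0.0001,0.0002,beta,862.67,4312487.33,1/yr,probability,statin safety review
mort_acute_cad,0.228,0.182,0.274,beta,73.91,250.27,1/yr,probability,acute coronary syndrome registry
mort_chronic_cad,0.07,0.067,0.072,beta,14100.39,187333.7529,1/yr,probability,chronic CAD cohort
hr_mort_cad_diabetes,1.81,1.44,2.28,lognormal,0.69,0.09,ratio,relative_effect,cohort study
mort_stroke_and_cad,0.075,0.05,0.1,beta,88.72,1094.73,1/yr,probability,assumption
mort_acute_ischemic_stroke,0.1,0.08,0.12,beta,86.34,777.02,1/yr,probability,stroke registry
mort_chronic_stroke,0.069,0.055,0.082,beta,89.39,1215.65,1/yr,probability,stroke cohort
rr_mort_stroke_diabetes,1.67,1.58,1.76,lognormal,0.8,0.18,ratio,relative_effect,cohort study
mort_acute_hemorrhagic_stroke,0.39,0.33,0.45,beta,98.62,154.25,1/yr,probability,stroke registry
hr_mort_diabetes,1.68,1.52,1.87,lognormal,0.51,0.09,ratio,relative_effect,cohort study
u_cad,0.79,0.73,0.86,beta,118.38,31.46,utility,utility,EQ-5D catalogue
u_myopathy,0.917,0.896,0.938,beta,697.06,54.95,utility,utility,EQ-5D catalogue
u_diabetes,0.8,0.62,0.98,beta,14.38,3.59,utility,utility,EQ-5D catalogue
u_stroke,0.63,0.44,0.78,beta,18.89,11.09,utility,utility,EQ-5D catalogue (shared ischemic/hemorrhagic)
du_acute_cad,0.041,0.021,0.062,beta,14.69,343.73,utility decrement,disutility,EQ-5D catalogue
du_acute_stroke,0.22,0.18,0.26,beta,90.42,320.59,utility decrement,disutility,EQ-5D catalogue
du_age_annual,0.004,0.002,0.006,beta,15.3,3809.93,utility decrement/yr,disutility,EQ-5D catalogue
cost_prs_test,145,116,174,gamma,96.04,0.66,USD,cost,vendor genotyping price
cost_standard_whp_screening,58,46,70,gamma,96.04,1.66,USD/yr,cost,"workplace biometric screening, gray literature"
cost_mobile_app,6,5,7,gamma,96.04,16.01,USD/yr,cost,vendor price
cost_primary_care_visit,114,91,137,gamma,96.04,0.84,USD,cost,medical expenditure panel survey
cost_statin,132,106,158,gamma,96.04,0.73,USD/yr,cost,online pharmacy prices
cost_background,4941,3953,5930,gamma,96.04,0.01943736086,USD/yr,cost,per-capita private insurance expenditure
cost_acute_cad_nonfatal,65442,43818,100531,gamma,20.46,0.0003126432566,USD,cost,US CVD cost study
cost_acute_cad_fatal,18246,14597,21896,gamma,96.04,0.0053,USD,cost,US CVD cost study
cost_acute_ischemic_stroke_nonfatal,40225,11539,100184,gamma,3.16,7.855811063e-05,USD,cost,US CVD cost study
cost_acute_ischemic_stroke_fatal,11256,9005,13507,gamma,96.04,0.0085,USD,cost,US CVD cost study
cost_acute_hemorrhagic_stroke_nonfatal,38246,30596,45895,gamma,96.04,0.0025,USD,cost,US CVD cost study
cost_acute_hemorrhagic_stroke_fatal,18246,14597,21896,gamma,96.04,0.0053,USD,cost,US CVD cost study
cost_followup_cad,11815,7865,16186,gamma,30.99,0.002622936945,USD/yr,cost,US CVD cost study
cost_followup_stroke,20005,16004,24006,gamma,96.04,0.0048,USD/yr,cost,US CVD cost study
cost_followup_myopathy,20438,16351,24536,gamma,96.04,0.0047,USD/yr,cost,statin myopathy cost study
cost_followup_diabetes,10026,8021,12031,gamma,96.04,0.0096,USD/yr,cost,diabetes cost study
cost_productivity_first_year_cad_stroke,73492,58794,88191,gamma,96.04,0.001306808904,USD,cost,absenteeism 73492/5 + presenteeism x4
cost_productivity_followup_cad_stroke,9056,7245,10868,gamma,96.04,0.01060512367,USD/yr,cost,chronic-condition absenteeism 9056/5 x5
cost_productivity_diabetes,9242,7393,11090,gamma,97.04,0.0104998918,USD/yr,cost,diabetes lost-productivity study
cost_productivity_followup_myopathy,9056,7245,10868,gamma,96.04,0.01060512367,USD/yr,cost,chronic-condition absenteeism 9056/5 x5
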