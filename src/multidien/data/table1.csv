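patient_id,sex,age_at_onset,baseline_sz_per_week,lead_laterality,implant_region,age_at_implant,lead_locations,duration_years,se_times,avg_stims_per_hour,pct_interp,pct_discarded,le_plv,cycle_period_days,analysis_flag
HUP047,M,10-19,87.5,R,N,50-59,frontal,4.38,10/10,36,0,2.05,0.16,31.17,both
HUP084,M,<10,2.57,B,M,50-59,L. Hipp/R. Hipp,4.92,10/10,57,0,1.65,0.17,12.37,both
HUP096,F,30-39,6.42,B,N,50-59,temporal,2.84,11/11,66,0.016,2.82,0.40,6.94,both
HUP108,M,10-19,1.75,B,M,30-39,L. Hipp/R. Hipp,3.36,10/10,62,0,2.40,0.24,7.35,stim_only
HUP109,M,40-49,70,B,M,60-69,L. Hipp/R. Hipp,2.15,10/10,65,0,3.69,0.18,31.17,both
HUP127,F,10-19,2.5,B,M,30-39,L. Hipp/R. Hipp,3.52,10/10,49,0,2.29,0.17,41.6,both
HUP128,F,10-19,8.5,L,N,60-69,temporal,2.32,10/10,92,0,9.30,0.05,49.47,both
HUP129,M,30-39,1.5,R,B,40-49,R. Hipp/R. Insula,3.09,11/11,22,0,2.60,0.07,24.74,both
HUP131,M,<10,17.5,L,B,20-29,frontal,3.41,10/10,49,0,4.28,0.24,46.7,both
HUP136,F,40-49,0.11,L,B,50-59,L. Frontal/L. Temp.,5.54,10/10,80,0,1.47,0.38,13.88,both
HUP137,M,30-39,3.15,B,M,50-59,L. Hipp/R. Hipp,3.72,10/10,75,0,2.17,0.42,11.02,both
HUP143,F,10-29,1.05,B,M,20-29,L. Hipp/R. Hipp,3.25,10/10,32,0,2.47,0.36,10.4,nostim_only
HUP147,F,10-29,14,L,N,40-49,parietal/insula,3.35,10/10,33,0,2.40,0.18,44.08,nostim_only
HUP153,F,40-49,0.58,B,M,50-59,L. Hipp/R. Hipp,3.12,10/10,41,0,2.57,0.27,29.42,both
HUP156,F,10-19,0.23,L,N,40-49,temporal,2.76,10/10,19,0,2.90,0.49,13.88,both
HUP197,F,<10,2,L,N,40-49,temporal,2.43,11/11,72,0,3.28,0.04,23.35,nostim_only
RNS021,F,<10,0.58,B,M,10-19,L. Hipp/R. Hipp,1.63,11/11,89,0,4.82,0.24,26.21,both
RNS022,F,10-19,1.87,B,M,30-39,L. Hipp/R. Hipp,3.36,"2,9/2,9",20,0,5.82,0.34,16.51,both
RNS026,M,20-29,0.23,B,M,20-29,L. Hipp/R. Hipp,2.37,11/11,33,0,3.36,0.18,17.49,both
RNS029,F,20-29,0.58,B,M,40-49,L. Hipp/R. Hipp,4.58,10/10,56,0,1.77,0.27,20.8,both
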