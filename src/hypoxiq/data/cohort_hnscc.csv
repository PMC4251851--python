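patient_id,suv,tumor_volume_cm3,fhv_pct,tp_ratio,blood_flow,ki67_pct,glut1_pct,p53_pct,hif1a_pct,cd68_pct,cd31_pct,tunel_pct,vegf_intensity,vital_status
1,18.5,8.3,9.5,0.91,35.3,17,5,70,0,27,2.5,19,3,dead
2,14.9,3.4,10.5,0.72,29.7,36,30,90,52,5,0.4,6,2,dead
3,19.0,34.1,61.6,1.41,44.4,82,10,80,16,26,0.6,10,2,dead
4,8.4,9.9,61.4,1.98,63.1,18,5,40,10,16,1.8,17,1,dead
5,17.3,401.6,39.2,1.49,44.8,60,5,95,0,13,5.7,0.3,2,dead
6,11.7,53.6,54.2,1.24,23.7,35,20,75,0,14,6.0,11,1,dead
7,7.6,1.7,17.8,0.95,12.4,85,40,25,58,7,6.8,10,2,alive
8,18.3,141.1,55.7,1.34,29.6,86,60,80,41,30,6.2,7,1,dead
9,13.0,22.2,48.0,1.07,NA,87,60,5,33,33,1.6,6,3,dead
10,7.8,5.5,50.5,1.11,26.2,28,0,75,1,30,2.6,NA,1,alive
11,28.8,23.6,19.7,1.00,19.7,80,0,90,1,38,4.7,7,2,alive
12,9.6,12.6,34.0,1.02,37.9,NA,NA,65,68,44,2.6,16,3,alive
13,7.2,5.0,10.1,0.82,24.3,NA,50,30,34,27,3.0,20,1,alive
14,19.6,52.6,63.2,1.37,41.0,35,50,2,23,9,14.9,10,2,dead
15,5.3,1.4,62.3,1.10,31.0,40,60,2,1,37,7.3,15,1,alive
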