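subject_id,night,setting,duration_h,actual_category,predicted_category,actual_ahi,predicted_ahi,actual_severity,predicted_severity
1,1,home_hsat,7.76,Abnormal,Abnormal,9.63,9.38,Mild,Mild
1,2,home_hsat,9.08,Abnormal,Abnormal,10.07,8.66,,
2,1,home_hsat,6.93,Abnormal,Abnormal,17.46,7.05,Moderate,Mild
2,2,home_hsat,5.35,Abnormal,Abnormal,16.16,9.71,,
3,1,home_hsat,3.56,Abnormal,Abnormal,12.49,10.51,Moderate,Moderate/Severe
4,1,home_hsat,8.15,Normal,Normal,3.61,<5,Normal,Normal
4,2,home_hsat,5.37,Normal,Normal,1.51,<5,,
5,1,home_hsat,4.83,Abnormal,Abnormal,31.42,23.23,Severe,Moderate/Severe
6,1,home_hsat,5.07,Normal,Abnormal,4.42,9.12,Normal,Mild
6,2,home_hsat,0.77,Normal,Normal,1.34,<5,,
7,1,home_hsat,5.00,Abnormal,Abnormal,5.70,13.19,Mild,Mild
7,2,home_hsat,1.40,Abnormal,Abnormal,5.07,10.20,,
8,1,home_hsat,8.57,Abnormal,Abnormal,5.11,8.53,Mild,Mild
9,1,home_hsat,1.54,Normal,Normal,4.02,<5,Normal,Mild
9,2,home_hsat,1.45,Normal,Abnormal,1.40,7.48,,
10,1,home_hsat,9.59,Normal,Normal,1.49,<5,Normal,Normal
10,2,home_hsat,9.05,Normal,Normal,2.14,<5,,
11,1,home_hsat,3.03,Normal,Normal,1.67,<5,Normal,Normal
12,1,home_hsat,2.82,Normal,Normal,2.17,<5,Normal,Normal
13,1,home_hsat,4.26,Abnormal,Abnormal,18.87,18.87,Moderate,Moderate/Severe
14,1,home_hsat,8.70,Normal,Normal,0.71,<5,Normal,Normal
14,2,home_hsat,5.88,Normal,Normal,0.18,<5,,
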