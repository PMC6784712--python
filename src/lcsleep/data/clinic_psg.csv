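subject_id,night,setting,duration_h,actual_category,predicted_category,actual_ahi,predicted_ahi,actual_severity,predicted_severity
1,1,clinic_psg,7.10,Abnormal,Abnormal,7.16,6.53,Mild,Mild
2,1,clinic_psg,0.00,,,,,,
3,1,clinic_psg,1.15,Abnormal,Abnormal,31.81,30.40,Severe,Moderate/Severe
4,1,clinic_psg,6.34,Abnormal,Abnormal,9.12,6.01,Mild,Mild
5,1,clinic_psg,1.12,Abnormal,Abnormal,73.43,15.32,Severe,Moderate/Severe
6,1,clinic_psg,7.33,Normal,Abnormal,3.60,9.92,Normal,Mild
7,1,clinic_psg,5.16,Abnormal,Normal,5.34,<5,Mild,Normal
8,1,clinic_psg,7.04,Normal,Abnormal,4.89,9.37,Normal,Mild
9,1,clinic_psg,5.65,Normal,Normal,3.06,<5,Normal,Normal
10,1,clinic_psg,6.93,Normal,Normal,2.20,<5,Normal,Normal
11,1,clinic_psg,6.21,Abnormal,Abnormal,12.11,10.30,Mild,Mild
12,1,clinic_psg,7.07,Abnormal,Abnormal,5.20,20.06,Mild,Moderate/Severe
13,1,clinic_psg,6.01,Abnormal,Normal,7.06,<5,Mild,Normal
14,1,clinic_psg,7.39,Normal,Normal,0.83,<5,Normal,Normal
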