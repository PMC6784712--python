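subject_id,night,setting,duration_h,actual_category,predicted_category,actual_ahi,predicted_ahi,actual_severity,predicted_severity
1,1,home_lc_only,,,Abnormal,,14.08,,Mild
1,2,home_lc_only,,,Abnormal,,9.47,,
2,1,home_lc_only,,,Abnormal,,10.38,,Mild
2,2,home_lc_only,,,Abnormal,,11.52,,
3,1,home_lc_only,,,Abnormal,,6.94,,Mild
3,2,home_lc_only,,,Normal,,<5,,
4,1,home_lc_only,,,Abnormal,,5.61,,Mild
4,2,home_lc_only,,,Normal,,<5,,
5,1,home_lc_only,,,Abnormal,,8.55,,Mild
5,2,home_lc_only,,,Abnormal,,14.72,,
6,1,home_lc_only,,,Normal,,<5,,Mild
6,2,home_lc_only,,,Abnormal,,6.63,,
8,1,home_lc_only,,,Abnormal,,13.07,,Mild
8,2,home_lc_only,,,Normal,,<5,,
9,1,home_lc_only,,,Normal,,<5,,Normal
9,2,home_lc_only,,,Normal,,<5,,
10,1,home_lc_only,,,Normal,,<5,,Mild
10,2,home_lc_only,,,Abnormal,,5.27,,
12,1,home_lc_only,,,Abnormal,,24.84,,Severe
12,2,home_lc_only,,,Normal,,<5,,
13,1,home_lc_only,,,Normal,,<5,,Mild
13,2,home_lc_only,,,Abnormal,,9.00,,
14,1,home_lc_only,,,Normal,,<5,,Normal
14,2,home_lc_only,,,Normal,,<5,,
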