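animal_id,group,lc_ml,fat_lc_ml,fat_fraction_pct,fat_infiltration
CNT 1,CNT,3.14,0.09,14.99,0.029
CNT 2,CNT,2.75,0.08,13.86,0.029
CNT 3,CNT,3.28,0.08,14.72,0.025
CNT 4,CNT,2.66,0.05,14.68,0.019
CNT 5,CNT,2.80,0.06,14.82,0.021
CNT 6,CNT,2.66,0.06,13.22,0.023
CNT 7,CNT,3.46,0.05,8.75,0.013
CNT 8,CNT,2.16,0.03,11.34,0.015
CNT 9,CNT,2.68,0.02,11.83,0.009
DM1 1,DM1,3.28,0.11,14.59,0.035
DM1 2,DM1,3.62,0.24,17.40,0.066
DM1 3,DM1,3.09,0.22,17.73,0.072
DM1 4,DM1,2.56,0.24,13.61,0.095
DM1 5,DM1,3.41,0.10,12.03,0.028
DM1 6,DM1,3.43,0.27,12.53,0.078
DM1 7,DM1,3.61,0.28,15.77,0.078
DM1 8,DM1,3.49,0.16,15.12,0.047
DM1 9,DM1,3.76,0.38,14.08,0.102
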