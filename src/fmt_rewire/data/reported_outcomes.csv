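patient_id,cohort,crp_w4,calpro_w4,response_w4,crp_w14,calpro_w14,remission_w14,endo_remission_w14
UC 1,UC,8.21,25.2,R,2.55,15.4,R,R
UC 2,UC,10.2,79.6,R,5.5,54.2,R,R
UC 3,UC,7.5,15,R,10.1,23,R,R
UC 4,UC,3.2,117.9,R,3.04,72,R,NR
UC 5,UC,7.5,342.9,R,4.1,98,R,NR
UC 6,UC,8.2,15,R,2.9,23.4,R,R
UC 7,UC,4.6,83.4,R,5.3,73.8,R,NR
UC 8,UC,6.3,15,R,5.6,18,R,R
UC 9,UC,10.0,41.5,R,8.7,15.4,R,R
UC 10,UC,4.3,29.9,R,2.26,37.5,R,R
UC 11,UC,5.3,93.2,R,2.03,123.9,R,NR
UC 12,UC,3.9,15,R,5.13,43,R,R
UC 13,UC,24.8,861.7,NR,7.3,362.7,NR,NR
UC 14,UC,15.5,125.9,NR,2.3,231.9,NR,NR
UC 15,UC,31.1,261.7,NR,6.86,321.6,NR,NR
CD 1,CD,2.2,34.6,R,4.0,36.4,R,R
CD 2,CD,3.08,62.4,R,9.7,42.6,R,R
CD 3,CD,5.2,23.8,R,3.32,28.3,R,R
CD 4,CD,4.9,53.3,R,7.1,33.5,R,R
CD 5,CD,4.2,16.7,R,5.22,37.6,R,R
CD 6,CD,3.8,20.4,R,6.55,24.0,R,R
CD 7,CD,5.5,19.7,R,5.03,17,R,R
CD 8,CD,6.3,49.1,R,3.10,19.4,R,R
CD 9,CD,15.8,117.1,R,2.3,231.5,R,NR
CD 10,CD,4.74,26.9,R,10.9,33.5,R,R
CD 11,CD,6.3,120.8,R,20.1,54.2,R,R
IFX 1,IFX-combo,3.6,129.7,R,2.08,72,R,R
IFX 2,IFX-combo,7.02,29.6,R,3.02,41.2,R,R
IFX 3,IFX-combo,5.1,66.6,R,4.23,52.3,R,R
IFX 4,IFX-combo,3.2,104.8,R,3.32,19.2,R,R
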