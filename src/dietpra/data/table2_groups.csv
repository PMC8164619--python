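group,intake_mean,intake_sd,intake_min,intake_max,bw_mean,bw_sd
"0-3 years, male",83.6,69.1,1.3,382.0,12.99,3.11
"0-3 years, female",69.9,90.4,3.3,376.8,12.84,3.18
"4-6 years, male",110.0,132.8,10.5,692.5,21.00,4.55
"4-6 years, female",81.1,85.1,1.7,358.8,20.03,4.42
"7-12 years, male",115.8,88.2,7.4,741.8,34.77,10.97
"7-12 years, female",83.9,68.5,3.4,440.3,33.22,10.66
"13-15 years, male",148.5,127.2,2.3,751.6,57.62,15.12
"13-15 years, female",96.5,94.6,6.2,475.5,50.44,10.60
"16-18 years, male",162.0,209.2,1.0,1428.3,65.98,15.10
"16-18 years, female",94.8,88.6,3.7,845.0,54.42,11.06
"19-65 years, male",171.2,170.4,4.4,1923.0,69.33,11.07
"19-65 years, female",108.4,115.8,2.1,725.2,57.27,9.75
">65 years, male",182.1,144.4,12.9,859.1,63.83,9.90
">65 years, female",142.9,88.1,4.1,1004.3,57.07,9.68
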