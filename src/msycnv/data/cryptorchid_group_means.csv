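group,n,ETSTY1,ETSTY2,ETSTY5,HSFY,RBMY,SRY,TSPY,UBA1Y
bi_CO,6,4.16,4.22,4.01,1.03,1.92,0.9,9.11,3.63
uni_CO,18,4.69,4.17,4.21,1.06,1.95,0.96,9.22,3.7
CO_all,24,4.55,4.18,4.16,1.05,1.94,0.94,9.19,3.68
normal_AQH,28,4.67,4.58,4.21,0.99,1.78,0.83,10.65,3.42
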