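breed,n,ETSTY1_mean,ETSTY1_sd,ETSTY2_mean,ETSTY2_sd,ETSTY5_mean,ETSTY5_sd,HSFY_mean,HSFY_sd,RBMY_mean,RBMY_sd,SRY_mean,SRY_sd,TSPY_mean,TSPY_sd,UBA1Y_mean,UBA1Y_sd
American Paint,1,3.60,,4.48,,4.26,,1.04,,1.77,,0.90,,9.80,,3.48,
Arabian,12,4.49,0.77,4.33,1.09,4.10,0.37,1.03,0.17,1.85,0.20,0.90,0.09,10.03,3.43,2.94,0.87
Caspian,6,4.73,0.48,4.53,0.69,4.08,0.21,0.97,0.07,1.88,0.21,0.84,0.12,9.67,1.17,3.57,0.55
Dales Pony,4,5.30,1.58,6.35,0.79,4.80,0.51,0.79,0.22,1.58,0.49,0.89,0.16,8.28,0.59,3.48,0.40
Estonian Native,28,4.49,1.26,5.93,2.48,5.76,5.90,1.15,0.48,2.15,0.43,1.21,0.46,12.98,7.04,4.09,2.39
Friesian,1,1.96,,3.78,,2.62,,0.85,,1.91,,0.78,,5.55,,3.13,
Haflinger,2,4.12,0.13,3.73,0.06,4.07,0.02,0.99,0.02,1.99,0.16,0.96,0.07,9.25,0.35,4.11,0.23
Icelandic,6,4.83,0.26,3.94,0.47,4.05,0.23,1.01,0.08,1.77,0.25,0.90,0.15,9.48,0.86,3.71,0.37
Lipizzan,10,5.10,0.36,3.85,0.28,3.90,0.09,0.95,0.09,1.91,0.17,0.96,0.03,8.73,0.31,3.99,0.22
Miniature,2,3.71,0.08,3.91,0.01,3.94,0.34,0.82,0.01,1.63,0.17,0.86,0.08,8.95,0.49,3.45,0.05
Mongolian,10,4.46,0.54,4.16,0.30,3.79,0.23,0.96,0.11,1.67,0.55,1.26,0.51,8.47,0.84,3.74,0.34
Noriker,4,4.91,0.65,3.92,0.12,3.89,0.05,0.98,0.07,1.92,0.11,0.98,0.06,8.68,0.49,4.00,0.08
Quarter Horse,28,4.64,0.75,4.59,0.85,4.21,0.49,1.00,0.15,1.79,0.23,0.83,0.11,10.66,2.62,3.43,0.52
Quarter Horse-Morgan mix,1,3.59,,4.50,,4.12,,0.98,,1.79,,0.93,,10.00,,3.51,
Shetland pony,5,5.10,0.20,4.25,0.69,4.21,0.44,0.94,0.05,1.73,0.43,0.80,0.27,8.37,0.50,3.80,
Standardbred,8,5.08,1.04,5.11,1.00,4.62,0.94,1.11,0.17,1.41,0.27,0.61,0.08,9.00,1.16,2.98,0.24
Suffolk Punch,8,3.89,0.17,4.50,0.31,4.12,0.24,1.02,0.11,1.87,0.13,0.82,0.09,9.32,1.19,3.44,0.32
Heck horse,7,5.86,1.26,6.17,0.81,4.99,0.40,1.10,0.08,1.34,0.46,0.74,0.11,15.36,2.64,3.56,0.45
Tennessee Walking,5,5.60,1.11,6.02,1.04,4.61,0.36,1.07,0.15,1.62,0.18,0.79,0.22,16.92,2.59,3.56,0.64
Thoroughbred,47,4.49,0.91,4.35,0.75,3.74,0.62,0.91,0.27,1.79,0.21,0.87,0.14,9.35,1.19,3.50,0.63
Yakutian,4,5.97,3.37,6.41,5.07,5.58,3.42,1.22,0.65,1.78,0.31,1.40,0.87,15.72,14.88,3.59,0.52
Zemaitukai,10,5.39,0.41,5.02,0.76,4.70,0.32,0.92,0.08,2.32,0.54,1.27,0.42,11.62,1.09,3.62,0.28
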