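breed,horse_id,sry_cn,rbmy_cn,confirmed_fertile
Estonian Native,BP364,1.96,2.81,0
Estonian Native,BP378,2.0,3.0,1
Estonian Native,BP379,1.74,2.685,0
Estonian Native,BP383,1.88,2.92,0
Estonian Native,BP384,1.49,2.66,0
Estonian Native,BP385,1.9,2.5,0
Estonian Native,BP386,1.58,2.35,1
Estonian Native,BP387,1.77,2.6,1
Estonian Native,BP388,1.55,2.85,1
Estonian Native,BP395,1.6,2.52,1
Estonian Native,BP399,1.76,2.53,1
Estonian Native,BP400,1.98,2.61,0
Mongolian,BP298,1.99,2.785,0
Mongolian,TR020,1.87,1.06,0
Mongolian,TR021,1.95,1.01,0
Yakutian,TR028,2.7,1.37,0
Zemaitukai,121576,1.7,2.8,1
Zemaitukai,121579,1.48,2.84,0
Zemaitukai,121581,1.66,2.77,0
Zemaitukai,121587,1.58,2.79,0
Zemaitukai,121589,1.89,2.93,0
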