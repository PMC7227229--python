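province,region
Liaoning,NEC
Jilin,NEC
Heilongjiang,NEC
Hebei,NC
Shanxi,NC
Shandong,NC
Henan,NC
Inner Mongolia,NC
Jiangsu,MLYR
Anhui,MLYR
Hubei,MLYR
Shaanxi,NWC
Gansu,NWC
Xinjiang,NWC
Chongqing,SSWC
Sichuan,SSWC
Guizhou,SSWC
Yunnan,SSWC
Guangxi,SSWC
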