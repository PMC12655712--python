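sex,age_days,L,M,S
male,0,0.250,3350.0,0.1250
male,7,0.250,3760.5,0.1244
male,14,0.250,4136.7,0.1238
male,21,0.250,4481.3,0.1232
male,28,0.250,4797.0,0.1227
male,35,0.250,5086.3,0.1221
male,42,0.250,5351.4,0.1215
male,49,0.250,5594.2,0.1209
male,56,0.250,5816.7,0.1203
male,63,0.250,6020.6,0.1197
male,70,0.250,6207.4,0.1192
male,77,0.250,6378.5,0.1186
male,84,0.250,6535.3,0.1180
male,91,0.250,6679.0,0.1174
male,98,0.250,6810.6,0.1168
male,105,0.250,6931.2,0.1163
male,112,0.250,7041.7,0.1157
male,119,0.250,7142.9,0.1151
male,126,0.250,7235.7,0.1145
male,133,0.250,7320.6,0.1139
male,140,0.250,7398.5,0.1133
male,147,0.250,7469.8,0.1128
male,154,0.250,7535.2,0.1122
male,161,0.250,7595.1,0.1116
male,168,0.250,7650.0,0.1110
male,175,0.250,7700.2,0.1104
male,182,0.250,7746.3,0.1100
male,189,0.250,7788.5,0.1100
male,196,0.250,7827.2,0.1100
female,0,0.250,3250.0,0.1250
female,7,0.250,3622.8,0.1244
female,14,0.250,3964.4,0.1238
female,21,0.250,4277.4,0.1232
female,28,0.250,4564.1,0.1227
female,35,0.250,4826.9,0.1221
female,42,0.250,5067.6,0.1215
female,49,0.250,5288.1,0.1209
female,56,0.250,5490.2,0.1203
female,63,0.250,5675.3,0.1197
female,70,0.250,5845.0,0.1192
female,77,0.250,6000.4,0.1186
female,84,0.250,6142.8,0.1180
female,91,0.250,6273.2,0.1174
female,98,0.250,6392.8,0.1168
female,105,0.250,6502.3,0.1163
female,112,0.250,6602.6,0.1157
female,119,0.250,6694.6,0.1151
female,126,0.250,6778.8,0.1145
female,133,0.250,6856.0,0.1139
female,140,0.250,6926.7,0.1133
female,147,0.250,6991.5,0.1128
female,154,0.250,7050.9,0.1122
female,161,0.250,7105.2,0.1116
female,168,0.250,7155.1,0.1110
female,175,0.250,7200.7,0.1104
female,182,0.250,7242.6,0.1100
female,189,0.250,7280.9,0.1100
female,196,0.250,7316.0,0.1100
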