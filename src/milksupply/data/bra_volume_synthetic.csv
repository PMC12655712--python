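band,cup,volume_cm3
8,AA,120
8,A,215
8,B,310
8,C,405
8,D,500
8,DD,595
8,E,690
8,F,785
8,G,880
10,AA,155
10,A,250
10,B,345
10,C,440
10,D,535
10,DD,630
10,E,725
10,F,820
10,G,915
12,AA,190
12,A,285
12,B,380
12,C,475
12,D,570
12,DD,665
12,E,760
12,F,855
12,G,950
14,AA,225
14,A,320
14,B,415
14,C,510
14,D,605
14,DD,700
14,E,795
14,F,890
14,G,985
16,AA,260
16,A,355
16,B,450
16,C,545
16,D,640
16,DD,735
16,E,830
16,F,925
16,G,1020
18,AA,295
18,A,390
18,B,485
18,C,580
18,D,675
18,DD,770
18,E,865
18,F,960
18,G,1055
20,AA,330
20,A,425
20,B,520
20,C,615
20,D,710
20,DD,805
20,E,900
20,F,995
20,G,1090
22,AA,365
22,A,460
22,B,555
22,C,650
22,D,745
22,DD,840
22,E,935
22,F,1030
22,G,1125
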