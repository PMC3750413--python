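category	lane4	lane5	lane6
total	62071296	38839694	69785822
spike	3128126	1554316	3693148
unmatched	23262622	12912128	22169416
m13_detected	17840274	12186625	21961629
bat_6bp	15859982	11258110	19398277
bat_5bp	591667	338953	984976
bat_4bp	304755	127279	440769
bat_lt4bp	788808	302764	891331
munged	32925286	23213290	40815100
mapped_BnaA.FAD2.a	1566912	1420311	2143813
mapped_BnaA.FAD2.b	6579001	4804826	8002197
mapped_BnaC.FAD2.a	791572	644265	1026912
mapped_BnaC.GL2.b	12302580	6167201	15136272
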