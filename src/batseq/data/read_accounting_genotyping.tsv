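category	reads
total	8002602
spike	89517
unmatched	6106250
m13_detected	1725988
bat_6bp	40277
bat_5bp	317373
bat_4bp	729019
bat_lt4bp	639319
munged	1086669
called	699449
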