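# Fixture: the eight newly predicted Kp(10)-bearing ORFs.
# Provenance: transcribed from the published comparative study. ORF
# lengths in bp as
# printed (eel 296/327; spotted gar 348/300; coelacanth 363/396/81; elephant
# shark 315). Motifs: eel Kp1 is followed by GK-Stop, coelacanth Kp3 by GKK,
# all others by GKR. The coelacanth Kiss3 ORF carries a stop codon seven
# amino-acids upstream of the Kp3(10) sequence (premature_stop=1).
species	gene	decapeptide	motif	orf_bp	premature_stop
european_eel	Kiss1	YNWNSFGLRY	GK-Stop	296	0
european_eel	Kiss2	FNRNPFGLRF	GKR	327	0
spotted_gar	Kiss1	YNWNSFGLRY	GKR	348	0
spotted_gar	Kiss2	FNFNPFGLRF	GKR	300	0
coelacanth	Kiss1	YNWNTFGLRY	GKR	363	0
coelacanth	Kiss2	FNFNPFGLRF	GKR	396	0
coelacanth	Kiss3	FNWNSFGLRF	GKK	81	1
elephant_shark	Kiss3	YNLNSFGLKF	GKR	315	0
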