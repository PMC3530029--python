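# Fixture: vertebrate Kp(10) decapeptide reference set.
# Provenance: the eight newly predicted decapeptides (status=new) are
# transcribed verbatim from the published comparative study (European eel
# Kp1/Kp2, spotted gar Kp1/Kp2, coelacanth Kp1/Kp2/Kp3, elephant shark
# Kp3); the 'unique' flag marks the four decapeptides reported there as
# novel among known Kp(10)s: eel Kp2 (Arg at position 3), coelacanth Kp1
# (Thr at position 5), coelacanth Kp3 (Phe-1 + Ser-5), elephant shark Kp3
# (Lys at position 9). The previously known entries (status=known) are
# reconstructed from the cited primary literature, the original alignment
# being unavailable in machine-readable form;
# they are chosen so that every non-novel new decapeptide has a previously
# known identical sequence (mouse-type YNWNSFGLRY; FNFNPFGLRF known from
# acanthopterygian Kiss2 and elephant shark Kiss2).
species	gene	decapeptide	status	unique
human	Kiss1	YNWNSFGLRF	known	0
mouse	Kiss1	YNWNSFGLRY	known	0
musk_shrew	Kiss1	YNRNSFGLRY	known	0
platypus	Kiss1	YNWNSFGLRY	known	0
platypus	Kiss2	FNFNPFGLRF	known	0
xenopus	Kiss1a	YNWNSFGLRY	known	0
xenopus	Kiss1b	YNWNSFGLRY	known	0
xenopus	Kiss2	FNFNPFGLRF	known	0
zebrafish	Kiss1	YNLNSFGLRY	known	0
zebrafish	Kiss2	FNYNPFGLRF	known	0
goldfish	Kiss1	YNLNSFGLRY	known	0
medaka	Kiss1	YNLNSFGLRY	known	0
medaka	Kiss2	FNFNPFGLRF	known	0
stickleback	Kiss2	FNFNPFGLRF	known	0
sea_lamprey	Kiss1	YNWNSFGLRY	known	0
elephant_shark	Kiss1	YNWNSFGLRY	known	0
elephant_shark	Kiss2	FNFNPFGLRF	known	0
european_eel	Kiss1	YNWNSFGLRY	new	0
european_eel	Kiss2	FNRNPFGLRF	new	1
spotted_gar	Kiss1	YNWNSFGLRY	new	0
spotted_gar	Kiss2	FNFNPFGLRF	new	0
coelacanth	Kiss1	YNWNTFGLRY	new	1
coelacanth	Kiss2	FNFNPFGLRF	new	0
coelacanth	Kiss3	FNWNSFGLRF	new	1
elephant_shark	Kiss3	YNLNSFGLKF	new	1
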