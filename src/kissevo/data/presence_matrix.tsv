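# Fixture: per-species Kiss/Kissr gene inventory (presence/absence).
# Provenance: transcribed from the published comparative study of
# kisspeptin-system evolution: four Kissr in spotted gar and
# coelacanth; three Kissr in European eel; two in zebrafish (Kissr-2,
# Kissr-3); one in stickleback (Kissr-2); Kissr-1/Kissr-4 in platypus;
# Kissr-4 in lizard; Kissr-1 (Kiss1r) in human; none in chicken. Three Kiss
# in coelacanth and Xenopus; two in eel, zebrafish, spotted gar, platypus;
# Kiss2 only in stickleback and lizard; Kiss1 only in human; none in
# chicken. Kiss4 has been observed in no species. Cells: 1 present,
# 0 absent, ? unknown.
species	Kiss1	Kiss2	Kiss3	Kiss4	Kissr-1	Kissr-2	Kissr-3	Kissr-4
european_eel	1	1	0	0	1	1	1	0
zebrafish	1	1	0	0	0	1	1	0
stickleback	0	1	0	0	0	1	0	0
spotted_gar	1	1	0	0	1	1	1	1
coelacanth	1	1	1	0	1	1	1	1
xenopus	1	1	1	0	1	1	1	0
lizard	0	1	0	0	0	0	0	1
chicken	0	0	0	0	0	0	0	0
platypus	1	1	0	0	1	0	0	1
human	1	0	0	0	1	0	0	0
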