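[Fixture: ten-species osteichthyan tree with WGD branch annotations, following the published comparative study's clade sequence: (1) vertebrates/osteichthyan root, actinopterygians vs sarcopterygians, teleosts (eel basal, then zebrafish+stickleback), tetrapods (xenopus, then diapsids lizard+chicken vs mammals platypus+human). 1R+2R annotate the root stem, the teleost-specific 3R the teleost stem.]
(((european_eel,(zebrafish,stickleback)clupeocephala)teleosts[&wgd=3R],spotted_gar)actinopterygians,(coelacanth,(xenopus,((lizard,chicken)diapsids,(platypus,human)mammals)amniotes)tetrapods)sarcopterygians)osteichthyans[&wgd=1R,2R];
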