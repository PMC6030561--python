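(Magnetococcus_marinus,((Rhodospirillum_rubrum,Rhodospirillum_centenum),((Rhodobacter_sphaeroides,Rhodobacter_capsulatus,Rhodovulum_sulfidophilum),(Rhodobium_orientis,Rhodoblastus_acidophilus,Rhodomicrobium_vannielii,(Afifella_marina,Afifella_pfennigii),(Rhodoplanes_elegans,Rhodoplanes_piscinae,Rhodoplanes_roseus),Rhodopseudomonas_palustris))));
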