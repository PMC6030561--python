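# Artifact-curated (synthetic) encoding of published ICM localization calls for the
# 14 purple nonsulfur bacteria surveyed by BChl autofluorescence; it is this
# package's own transcription, not a deposited data file. Orders: Rhodospirillum =
# Rhodospirillales; Rhodobacter/Rhodovulum = Rhodobacterales; the remainder =
# Rhizobiales. Magnetococcus_marinus (outgroup, no ICM) is intentionally absent.
species,localization
Rhodospirillum_rubrum,nonrestricted
Rhodospirillum_centenum,nonrestricted
Rhodobacter_sphaeroides,nonrestricted
Rhodobacter_capsulatus,nonrestricted
Rhodovulum_sulfidophilum,nonrestricted
Rhodobium_orientis,nonrestricted
Rhodoblastus_acidophilus,nonrestricted
Rhodomicrobium_vannielii,restricted
Afifella_marina,restricted
Afifella_pfennigii,restricted
Rhodoplanes_elegans,restricted
Rhodoplanes_piscinae,restricted
Rhodoplanes_roseus,restricted
Rhodopseudomonas_palustris,restricted
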