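# Record inventory of the chimera-free phylogenetic alignment
# (data-set I): 45 database sequences + 12 newly sequenced Lachninae
# samples + 4 Serratia symbiotica outgroup sequences = 61 records.
# Record names for the database and outgroup subsets are synthetic
# placeholders; the per-source counts are as published.
record	source
database_sp01	database
database_sp02	database
database_sp03	database
database_sp04	database
database_sp05	database
database_sp06	database
database_sp07	database
database_sp08	database
database_sp09	database
database_sp10	database
database_sp11	database
database_sp12	database
database_sp13	database
database_sp14	database
database_sp15	database
database_sp16	database
database_sp17	database
database_sp18	database
database_sp19	database
database_sp20	database
database_sp21	database
database_sp22	database
database_sp23	database
database_sp24	database
database_sp25	database
database_sp26	database
database_sp27	database
database_sp28	database
database_sp29	database
database_sp30	database
database_sp31	database
database_sp32	database
database_sp33	database
database_sp34	database
database_sp35	database
database_sp36	database
database_sp37	database
database_sp38	database
database_sp39	database
database_sp40	database
database_sp41	database
database_sp42	database
database_sp43	database
database_sp44	database
database_sp45	database
Cinara_bungeanae	study
Cinara_formosana_1	study
Cinara_formosana_2	study
Cinara_pinikoraiensis	study
Cinara_piniphila	study
Lachnus_quercihabitans	study
Lachnus_siniquercus	study
Maculolachnus_submacula	study
Nippolachnus_piri	study
Stomaphis_betulidahuricae	study
Stomaphis_quercisucta	study
Stomaphis_sinisalicis	study
Serratia_symbiotica_1	outgroup
Serratia_symbiotica_2	outgroup
Serratia_symbiotica_3	outgroup
Serratia_symbiotica_4	outgroup
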