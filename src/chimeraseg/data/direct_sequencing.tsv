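# Direct-sequencing outcome per sample in the same 12-sample Lachninae
# survey: 2 of 12 PCR products gave single-peak chromatograms (effective),
# 10 showed miscellaneous peaks.  Which two samples were the effective
# ones is not identifiable from the published summary; the assignment to
# sample ids below is an arbitrary (synthetic) placeholder.
sample_id	effective
sample_01	true
sample_02	true
sample_03	false
sample_04	false
sample_05	false
sample_06	false
sample_07	false
sample_08	false
sample_09	false
sample_10	false
sample_11	false
sample_12	false
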