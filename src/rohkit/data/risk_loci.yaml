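# Histiocytic-sarcoma risk loci and their haplotype-defining SNV positions
# (UU_Cfam_GSD_1.0 coordinates).
- label: chr5_33Mb
  chrom: "5"
  defining_positions: [33855429, 33993463, 34005879, 34012145, 34028329,
                       34043717, 34076942, 34083675, 34087262, 34087720,
                       34100829, 34103314, 34109473, 34120114, 34421555,
                       34425934, 34428714, 34433959, 34434313, 34436053,
                       34440306, 34440578, 34442862, 34448188, 34449394,
                       34455245, 34529929]
- label: chr11_41Mb
  chrom: "11"
  defining_positions: [41258181, 41275129, 41275213, 41277330, 41280608,
                       41290542, 41298930, 41306401, 41310312, 41313739,
                       41317800, 41329384, 41330760, 41332109, 41366494]
- label: chr11_44Mb
  chrom: "11"
  defining_positions: [43510563, 43519952, 43537944, 43565114, 43939450,
                       44316022, 44342776, 44343823, 44344884, 44366118,
                       44371942, 44374045, 44380626, 44395661, 44397515,
                       44609562, 44611627, 44612055]
- label: chr14_11Mb
  chrom: "14"
  defining_positions: [10887016, 10889217, 10891570, 10893694, 10895560,
                       10898604, 10906919, 10932956, 10936449, 10943176,
                       10949045, 10958187, 10960590, 10974467]
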