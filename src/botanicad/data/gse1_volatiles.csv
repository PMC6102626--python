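# Volatile constituents of the same grape seed extract (GSE-1) by GC-FID / GC-HRMS:
# the eight FID peaks whose per-dose mass exceeds the threshold of toxicological
# concern, with chemical-ionization accurate masses and Kovats retention indexes.
fid_peak,kovats_ri,accurate_mz,ppm,identification,formula,amount_ug_per_dose,confidence
1,732,87.0441,-0.006,Unidentified,C4H6O2,170,partial
2,894,91.0390,0.192,Dihydroxyacetone,C3H6O3,710,reference
3,966,91.0390,0.039,Glycerol,C3H8O3,980,reference
4,1188,111.0441,0.216,Catechol,C6H6O2,850,reference
5,1284,125.0597,-0.288,4-methyl catechol,C7H8O2,190,reference
6,1362,127.0390,-0.084,"1,2,3-benzenetriol",C6H6O3,770,reference
7,1593,153.0543,-1.768,Unidentified,C8H8O3,620,partial
8,1801,165.0544,-1.579,Unidentified,C9H8O3,230,partial
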