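feature	haplotype	chrom	start	end
hap1_exclusive_deletion	hap1	chr5	9909454	11184824
inversion_1	hap1	chr5	3795373	5046405
inversion_1	hap2	chr5	3693006	5080743
inversion_2	hap1	chr5	5255881	6414969
inversion_2	hap2	chr5	5155099	6423723
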