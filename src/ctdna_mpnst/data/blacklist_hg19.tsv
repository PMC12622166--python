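chrom	start	end	name
1	121400000	121535434	pericentromeric_chr1
2	90500000	91000000	lowcomplexity_chr2
17	22200000	22300000	pericentromeric_chr17
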