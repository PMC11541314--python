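# The 21-SNP synergistic cluster reported by the MDR interaction network,
# given as SNP numbers of the SNP-number map (one per line, in reported
# order). Mapping through that table yields 14 unique genes.
SNP21
SNP22
SNP41
SNP34
SNP45
SNP18
SNP19
SNP32
SNP10
SNP26
SNP25
SNP51
SNP24
SNP2
SNP35
SNP11
SNP53
SNP29
SNP3
SNP15
SNP27
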