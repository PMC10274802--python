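cell_label,dataset_cell_id,Hdc,Antp,Ubx
MsN1,Rep2_TACCTATTCAACACGT,9.27,10.59,0
MsN2,Rep2_GTGGGTCGTCCGTCAG,11.21,11.38,0
MsN3,Rep3_GGTATTGCAAGCCATT,10.97,10.12,0
MsN4,Rep3_TAGGCATTCCATGCTC,10.46,11.05,0
MsN5,Rep3_TCACAAGCATCGGAAG,10.67,10.62,0
MtN1,Rep4_AAACGGGAGTTGTCGT,10.47,0,9.83
MtN2,Rep4_CACCTTGCAAGCTGGA,10.93,0,12.28
MtN3,Rep4_CGGGTCAAGGGCTCTC,9.19,6.88,10.77
MtN4,Rep4_GGCGTGTGTATCTGCA,9.95,0,11.03
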