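dataset,cell,postsynaptic_sites,upstream_valid_connections,presynaptic_sites,downstream_connections,downstream_valid,downstream_orphan,downstream_undetermined
FANC,MsAHN-L,1040,992,1664,4604,995,93,3516
FANC,MsAHN-R,962,899,1170,3183,740,60,2383
FANC,MtAHN-L,1430,1288,2586,7580,1317,505,5758
FANC,MtAHN-R,1024,935,1952,4901,891,292,3718
MANC,MsAHN-L,2941,2825,1782,5090,,,
MANC,MsAHN-R,3116,2984,1722,5001,,,
MANC,MtAHN-L,4039,3499,2102,4946,,,
MANC,MtAHN-R,4895,4173,2549,6032,,,
FAFB,MsAHN-L,92,,1115,3427,1649,407,1371
FAFB,MtAHN-L,70,,556,1440,812,215,413
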