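location,region,group,n_female,n_hybrid_female,n_male,n_diploid_male,n_triploid_male,n_hybrid_male
SP_VI,iberian,lusitanicus,0,0,3,1,0,0
SP_PO,iberian,lusitanicus,7,0,4,0,0,0
SP_BU,iberian,lusitanicus,7,2,0,0,0,0
SP_PA,iberian,lusitanicus,5,0,0,0,0,0
SP_SO,iberian,lusitanicus,9,2,2,0,0,0
PT_BR,iberian,lusitanicus,3,0,4,0,0,0
PT_VC,iberian,lusitanicus,14,1,0,0,0,0
SP_SG1,iberian,lusitanicus,10,1,0,0,0,0
SP_SG2,iberian,lusitanicus,67,6,71,5,1,9
SP_SG3,iberian,lusitanicus,23,2,10,0,0,2
SP_SG3,iberian,morph_hybrid,1,0,1,0,0,0
SP_MA,iberian,lusitanicus,9,0,3,2,0,0
SP_MU1,iberian,lusitanicus,16,4,7,2,0,3
SP_MU2,iberian,lusitanicus,18,7,7,2,0,4
SP_HU,iberian,lusitanicus,2,1,5,0,0,2
SP_SN1,iberian,lusitanicus,8,1,8,0,0,1
SP_SN1,iberian,terrestris,0,0,1,0,0,1
SP_SN2,iberian,lusitanicus,15,3,25,0,0,4
SP_SN2,iberian,morph_hybrid,0,0,4,0,0,0
SP_SN2,iberian,terrestris,4,3,0,0,0,0
SP_SN3,iberian,lusitanicus,27,6,24,1,0,10
SP_SN3,iberian,terrestris,11,5,2,0,0,2
REF_BL,reference,terrestris,12,0,0,0,0,0
REF_FR,reference,terrestris,18,3,5,0,0,0
PN_AM,pyrenees,lusitanicus,14,5,0,0,0,0
PN_AM,pyrenees,terrestris,1,1,0,0,0,0
PN_EY,pyrenees,lusitanicus,15,6,0,0,0,0
PN_EY,pyrenees,terrestris,4,3,0,0,0,0
PN_JA,pyrenees,lusitanicus,1,1,0,0,0,0
PN_JA,pyrenees,morph_hybrid,4,0,0,0,0,0
REF_SP80,historical,lusitanicus,40,1,4,0,0,0
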