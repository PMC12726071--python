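CDR3_alpha,CDR3_beta,Epitope,Pathology,Source
CAVMDSNYQLIW,CASSEGGSNEQFF,5-OP-RU,M. tuberculosis,SYN001
CAVRDSNYQLIW,,5-OP-RU,M. tuberculosis,SYN002
CAVSDSNYQLIW,CASSDRVNEQFF,5-OP-RU,M. tuberculosis,SYN003
CAVKDSNYQLIW,,riboflavin intermediate,M. tuberculosis,SYN004
CAVNNDYKLSF,CASSLGQAYEQYF,5-OP-RU,M. tuberculosis,SYN005
CAVMSSYKLIF,,5-OP-RU,M. tuberculosis,SYN006
,CASSLAPGATNEKLFF,NLVPMVATV,Cytomegalovirus,SYN007
CAGNTGKLIF,CASSIRSSYEQYF,NLVPMVATV,Cytomegalovirus,SYN008
,CASSVRSTDTQYF,DQ2.5-glia-alpha1,Celiac disease,SYN009
CAVGGGSGGSYIPTF,CASSFGREQYF,DQ2.5-glia-omega2,Celiac disease,SYN010
CAGAGGGADGLTF,,GILGFVFTL,Influenza,SYN011
CILRDGRLYF,CASSPTSGGQETQYF,NY-ESO-1,Cancer,SYN012
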