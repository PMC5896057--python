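Name,EvidenceFor,Type,isPresent,Source,Label,Description
Comp_Evidence_61339,Evidence_61339,Computation,true,TIGRFAM,TIGR01139,protein-family model hit for cysteine synthase
Exp_GenProp0305,GenProp0305,Experimentation,true,Prototrophy,cysteine prototrophy,organism grows without supplemented cysteine
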