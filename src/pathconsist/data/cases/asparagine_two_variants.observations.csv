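Name,EvidenceFor,Type,isPresent,Source,Label,Description
Exp_UPA00134,UPA00134,Experimentation,true,Prototrophy,asparagine prototrophy,organism grows without supplemented asparagine
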