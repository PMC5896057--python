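Name,EvidenceFor,Type,isPresent,Source,Label,Description
Comp_UER01033,UER01033,Computation,true,UniProtKB,aspartate--tRNA ligase,annotated non-discriminating aspartyl-tRNA synthetase
Comp_UER01034,UER01034,Computation,true,UniProtKB,Asp-tRNA(Asn) formation,annotated mischarged tRNA formation step
Exp_UPA00134,UPA00134,Experimentation,true,Prototrophy,asparagine prototrophy,organism grows without supplemented asparagine
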