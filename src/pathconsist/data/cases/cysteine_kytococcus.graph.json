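{
  "concepts": [
    {"id": "GenProp0305", "label": "cysteine biosynthesis", "category": "pathway", "dispensable": false},
    {"id": "GenProp0304", "label": "cysteine biosynthesis, tRNA-dependent", "category": "variant", "dispensable": false},
    {"id": "GenProp0218", "label": "cysteine biosynthesis from serine", "category": "variant", "dispensable": false},
    {"id": "Component_CysSynthase", "label": "cysteine synthase", "category": "component", "dispensable": false},
    {"id": "Component_SerAcetyl", "label": "serine O-acetyltransferase", "category": "component", "dispensable": false},
    {"id": "Evidence_61339", "label": "TIGR01139", "category": "functional-unit", "dispensable": false},
    {"id": "Evidence_61340", "label": "TIGR01172", "category": "functional-unit", "dispensable": false}
  ],
  "relations": [
    {"parent": "GenProp0305", "child": "GenProp0304", "kind": "subtype"},
    {"parent": "GenProp0305", "child": "GenProp0218", "kind": "subtype"},
    {"parent": "GenProp0218", "child": "Component_CysSynthase", "kind": "part"},
    {"parent": "GenProp0218", "child": "Component_SerAcetyl", "kind": "part"},
    {"parent": "Component_CysSynthase", "child": "Evidence_61339", "kind": "subtype"},
    {"parent": "Component_SerAcetyl", "child": "Evidence_61340", "kind": "subtype"}
  ]
}
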