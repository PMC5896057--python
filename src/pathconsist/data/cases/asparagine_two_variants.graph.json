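{
  "concepts": [
    {"id": "UPA00134", "label": "L-asparagine biosynthesis", "category": "pathway", "dispensable": false},
    {"id": "VAR00134-1", "label": "via asparagine synthase (glutamine-hydrolysing)", "category": "variant", "dispensable": false},
    {"id": "VAR00134-2", "label": "via aspartate--ammonia ligase", "category": "variant", "dispensable": false},
    {"id": "UER00194", "label": "L-aspartate + L-glutamine -> L-asparagine + L-glutamate", "category": "functional-unit", "dispensable": false},
    {"id": "UER00195", "label": "L-aspartate + NH4(+) -> L-asparagine", "category": "functional-unit", "dispensable": false}
  ],
  "relations": [
    {"parent": "UPA00134", "child": "VAR00134-1", "kind": "subtype"},
    {"parent": "UPA00134", "child": "VAR00134-2", "kind": "subtype"},
    {"parent": "VAR00134-1", "child": "UER00194", "kind": "part"},
    {"parent": "VAR00134-2", "child": "UER00195", "kind": "part"}
  ]
}
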