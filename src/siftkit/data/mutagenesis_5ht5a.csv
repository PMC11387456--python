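generic_label,substitution,effect,ligand
3x32,D3x32A,loss,serotonin
3x33,V3x33A,decrease,serotonin
7x42,Y7x42A,loss,serotonin
7x38,L7x38A,mixed,various
2x64,E2x64D,mixed,CHEMBL3654198
2x64,E2x64Q,mixed,CHEMBL3654198
2x64,E2x64A,mixed,lysergide
6x52,F6x52A,decrease,serotonin
5x43,S5x43A,mixed,various
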