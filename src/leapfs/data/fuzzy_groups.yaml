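# Fuzzy amino-acid groups for transitive annotation transfer, v1.
# A reconstruction of the CSA-style homologous-residue equivalence
# classes; annotations cross aligned positions only within one group.
# Override by passing a file of the same shape to load_fuzzy_groups.
groups:
  - [ASP, GLU]
  - [LYS, ARG, HIS]
  - [SER, THR]
  - [ASN, GLN]
  - [ILE, LEU, VAL, MET]
  - [PHE, TYR, TRP]
  - [ALA, GLY]
  - [CYS]
  - [PRO]
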