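name: Res21-Q
residues:
  - {res: ALA143, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: LEU144, charge: 0, retain: whole_fragment, frozen: [CA], bridging: true}
  - {res: TYR145, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: ASP173, charge: -1, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: SER174, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: GLN175, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: GLU212, charge: -1, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: ASP214, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: GLN217, charge: 1, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: THR226, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: HIS228, charge: 1, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: ARG251, charge: 1, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: ASP257, charge: -1, retain: whole_fragment, frozen: [CA], bridging: true}
  - {res: PRO258, charge: 0, retain: whole_fragment, frozen: [CA]}
  - {res: ASP259, charge: 0, retain: whole_fragment, frozen: [CA]}
  - {res: GLY260, charge: 0, retain: whole_fragment, frozen: [CA], bridging: true}
  - {res: TRP367, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: TRP376, charge: 0, retain: sidechain_Calpha, frozen: [CA, CB]}
  - {res: BGC1, charge: 0, retain: whole_fragment}
  - {res: BGC2, charge: 0, retain: whole_fragment}
  - {res: HOH901, charge: 0, retain: whole_fragment}
  - {res: HOH902, charge: 0, retain: whole_fragment}
  - {res: HOH903, charge: 0, retain: whole_fragment}
  - {res: HOH904, charge: 0, retain: whole_fragment}
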