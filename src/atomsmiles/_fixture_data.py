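"""Pinned fixture molecule sets.

All strings are stored in the reference canonical dialect (the bundled
parser's default canonical SMILES), so the string-level round-trip
contract applies to every entry. The sets probe complementary structural
regimes: small organic drugs (aromatics, heteroatoms, stereocentres,
charges), plain chains (the high-repetition regime), ring systems
(aromatic and saturated heterocycles, fused rings), and the 18
constitutional isomers of octane (pure configurational variation at a
fixed formula C8H18).
"""

DRUGLIKE_SMALL = (
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "CC(=O)Nc1ccc(O)cc1",
    "O=C(O)c1ccccc1O",
    "Clc1ccccc1C1=NCc2nncn2-c2ccccc21",
    "CN1CCC[C@H]1c1cccnc1",
    "COc1ccc2cc([C@@H](C)C(=O)O)ccc2c1",
    "NC(=O)c1ccc[nH]1",
    "Oc1ccc(CC2NCCc3cc(O)c(O)cc32)cc1",
    "NC(Cc1ccc(O)c(O)c1)C(=O)O",
    "C[C@@H](N)C(=O)O",
    "O=C(O)[C@@H]1CCCN1",
    "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
    "N[C@@H](Cc1ccccc1)C(=O)O",
    "N=C(N)NCCC[C@H](N)C(=O)O",
    "OCC(O)CO",
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "CC(C)NCC(O)COc1cccc2ccccc12",
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CC(N)Cc1ccccc1",
    "CNC(C)Cc1ccccc1",
    "NC(=O)c1cccnc1",
    "O=C(O)c1cccnc1",
    "Nc1ccc(S(N)(=O)=O)cc1",
    "CC(=O)Nc1ccc(S(N)(=O)=O)cc1",
    "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "Cn1ccc(N)nc1=O",
    "Cc1cn(C)c(=O)[nH]c1=O",
    "O=c1[nH]cnc2[nH]cnc12",
    "OCC1OC(O)C(O)C(O)C1O",
    "O=C(O)CC(O)(CC(=O)O)C(=O)O",
    "O=C(O)C=CC(=O)O",
    "CC(=O)OCC(COC(C)=O)OC(C)=O",
    "CCOC(=O)c1ccccc1N",
    "COC(=O)c1ccccc1O",
    "Oc1ccccc1",
    "Oc1ccc(Cl)cc1",
    "OCCOCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1",
    "CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2",
    "CNCCCOC(c1ccc(F)cc1)c1ccc(C(F)(F)F)cc1",
    "NCCc1c[nH]c2ccc(O)cc12",
    "NCCc1ccc(O)c(O)c1",
    "O=C(NC(CO)C(O)c1ccc([N+](=O)[O-])cc1)C(Cl)Cl",
    "CN1CCC(=C2c3ccccc3CCc3ccccc32)CC1",
    "O=C(O)c1cc(O)c(O)c(O)c1",
    "COc1ccc(CCN)cc1",
    "CC(C)(C)c1ccc(O)cc1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "O=S(=O)(c1ccccc1)N1CCCCC1",
    "CC1=CC(=O)CC(C)(C)C1",
    "CC(=O)c1ccc2ccccc2c1",
    "[NH3+]c1ccccc1C(=O)[O-]",
    "C[N+](C)(C)CC(O)CC(=O)[O-]",
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",
    "Cc1ccc(S(=O)(=O)NC(=O)NN2CCCCCC2)cc1",
)

LINEAR_CHAINS = (
    "CC",
    "CCC",
    "CCCC",
    "CCCCC",
    "CCCCCC",
    "CCCCCCC",
    "CCCCCCCC",
    "CCCCCCCCC",
    "CCCCCCCCCC",
    "CCCCCCCCCCC",
    "CCCCCCCCCCCC",
    "CCO",
    "CCCO",
    "CCCCO",
    "CCCCCO",
    "CCCCCCO",
    "CC(=O)O",
    "CCC(=O)O",
    "CCCC(=O)O",
    "CCCCCC(=O)O",
    "CCCCCCCC(=O)O",
    "CCCCCCCCCC(=O)O",
    "CCN",
    "CCCN",
    "CCCCN",
    "CCCCCCN",
    "CCOCC",
    "CCCOCC",
    "COC",
    "CCS",
    "CCSCC",
    "C=C",
    "C=CC=C",
    "CC=CC",
    "C#N",
    "CC#N",
    "CC#CC",
    "F/C=C/F",
    "C/C=C/C(=O)O",
    "OCCO",
    "OCCCO",
    "OCCOCCO",
)

RING_PROBES = (
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1c[nH]cn1",
    "c1cn[nH]c1",
    "c1cocn1",
    "c1cscn1",
    "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1",
    "c1cnc2[nH]cnc2c1",
    "c1ncc2nc[nH]c2n1",
    "c1ccc2c(c1)oc1ccccc12",
    "c1ccc2c(c1)sc1ccccc12",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc(Oc2ccccc2)cc1",
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "C1CCCCC1",
    "C1CCCCCC1",
    "C1CCC2CCCCC2C1",
    "C1CCC2(CC1)CCCCC2",
    "C1CN1",
    "C1CO1",
    "C1CCNC1",
    "C1CCOC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CNCCN1",
    "C1COCCN1",
    "C1CSCCN1",
    "O=C1CCCCC1",
    "O=C1CCCN1",
    "O=c1cc[nH]c(=O)[nH]1",
    "C1=CCCCC1",
    "C1=CCCC=C1",
)

OCTANE_ISOMERS = (
    "CCCCCCCC",
    "CCCCCC(C)C",
    "CCCCC(C)CC",
    "CCCC(C)CCC",
    "CCCCC(C)(C)C",
    "CCCC(C)C(C)C",
    "CCC(C)CC(C)C",
    "CC(C)CCC(C)C",
    "CCCC(C)(C)CC",
    "CCC(C)C(C)CC",
    "CCCC(CC)CC",
    "CCC(C)C(C)(C)C",
    "CC(C)CC(C)(C)C",
    "CCC(C)(C)C(C)C",
    "CC(C)C(C)C(C)C",
    "CCC(CC)C(C)C",
    "CCC(C)(CC)CC",
    "CC(C)(C)C(C)(C)C",
)

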