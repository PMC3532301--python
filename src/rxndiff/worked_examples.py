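"""Worked-example reactions with literature structures.

Four small KEGG reactions whose compound structures are drawn in the
original method description; they anchor the fingerprint dialect:

* R00005 — urea-1-carboxylate amidohydrolase: the hand-enumerable
  difference fingerprint at path length 1;
* R00260 — glutamate racemase: the canonical zero-difference-fingerprint
  (filter category 6) example;
* R00683 / R02910 — SAM-dependent N-methyltransferases whose difference
  fingerprints at path length 3 sit at the published minimum Euclidean
  distance (2 on the directed-counting distance scale).

Structures are given as stereo-annotated SMILES; the parser discards the
stereo, which is exactly what makes R00260's fingerprint vanish.
"""
from __future__ import annotations

from .chemgraph import MoleculeGraph, parse_molecule
from .dataset import ECLabel, Reaction

#: KEGG compound id -> SMILES.
COMPOUND_SMILES: dict[str, str] = {
    # R00005: urea-1-carboxylate + H2O <=> 2 CO2 + 2 NH3
    "C01010": "NC(=O)NC(=O)O",      # urea-1-carboxylate
    "C00001": "O",                  # water
    "C00011": "O=C=O",              # carbon dioxide
    "C00014": "N",                  # ammonia
    # R00260: L-glutamate <=> D-glutamate
    "C00025": "N[C@@H](CCC(=O)O)C(=O)O",   # L-glutamate
    "C00217": "N[C@H](CCC(=O)O)C(=O)O",    # D-glutamate
    # R00683 / R02910 cofactor pair
    "C00019": "C[S+](CC[C@H](N)C(=O)O)C[C@H]1O[C@@H](n2cnc3c(N)ncnc23)[C@H](O)[C@@H]1O",  # S-adenosyl-L-methionine
    "C00021": "N[C@@H](CCSC[C@H]1O[C@@H](n2cnc3c(N)ncnc23)[C@H](O)[C@@H]1O)C(=O)O",       # S-adenosyl-L-homocysteine
    # R00683: SAM + L-tryptophan <=> SAH + abrine (N-methyl-L-tryptophan)
    "C00078": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",    # L-tryptophan
    "C03137": "CN[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",   # abrine
    # R02910: SAM + serotonin <=> SAH + N-methylserotonin
    "C00780": "NCCc1c[nH]c2ccc(O)cc12",              # serotonin
    "C05659": "CNCCc1c[nH]c2ccc(O)cc12",             # N-methylserotonin
}

R00005 = Reaction(
    id="R00005",
    reactants=((1, "C01010"), (1, "C00001")),
    products=((2, "C00011"), (2, "C00014")),
    ec=ECLabel((3, 5, 1)),
)

R00260 = Reaction(
    id="R00260",
    reactants=((1, "C00025"),),
    products=((1, "C00217"),),
    ec=ECLabel((5, 1, 1)),
)

R00683 = Reaction(
    id="R00683",
    reactants=((1, "C00019"), (1, "C00078")),
    products=((1, "C00021"), (1, "C03137")),
    ec=None,  # 'enzyme not yet characterized'
)

R02910 = Reaction(
    id="R02910",
    reactants=((1, "C00019"), (1, "C00780")),
    products=((1, "C00021"), (1, "C05659")),
    ec=ECLabel((2, 1, 1)),
)


def compound_graphs() -> dict[str, MoleculeGraph]:
    """Parse all worked-example structures into molecular graphs."""
    return {cid: parse_molecule(smi, "smiles", id=cid)
            for cid, smi in COMPOUND_SMILES.items()}
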