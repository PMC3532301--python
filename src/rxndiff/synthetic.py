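"""Synthetic labelled reaction sets with controllable class structure.

Every other module is testable without downloading any corpus: a small
library of hand-curated scaffolds (<= 12 heavy atoms) is combined with
transformation templates — structural edit rules standing in for enzyme
sub-subclasses — to emit elementally balanced, fully structured, EC-labelled
reactions in the dataset module's TSV formats.

The default templates were chosen so the resulting class structure probes
the classifier at different fragment path lengths:

* N-methylation (EC 2.1.1, methanol donor) and alcohol amination
  (EC 2.6.1) share the *identical* difference fingerprint
  ``{C-O:+1, C-N:-1}`` at path length 1 and separate only at length >= 2,
  so a length sweep shows short fragments failing to discriminate;
* ester hydrolysis (3.1.1), secondary-alcohol oxidation (1.1.1) and
  phosphotransfer (2.7.1, pyrophosphate-type donor) conserve the length-1
  bond inventory: their fingerprints are all-zero at length <= 1 and those
  reactions fall to filter category 6 there;
* decarboxylation (4.1.1) is recognisable at every length >= 1.

Each template's site pattern confines it to a homologous substrate series
(its "substrate specificity"), which keeps within-class fingerprint spread
below the smallest between-class gap at path length 3 — the geometry the
nearest-neighbour classifier assumes of real sub-subclasses.

A racemase template (5.1.1) flips one stereocentre and therefore has a zero
difference fingerprint at every length; it is emitted only when explicitly
requested, to exercise filter category 6.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from rdkit import Chem

from .chemgraph import MoleculeGraph, from_rdkit
from .dataset import ECLabel, Reaction, write_compounds_tsv, write_reactions_tsv
from .errors import TemplateError

EditFn = Callable[[Chem.RWMol, tuple[int, ...]], Chem.Mol]
SiteFn = Callable[[Chem.Mol], list[tuple[int, ...]]]


@dataclass(frozen=True)
class TransformationTemplate:
    """A structural edit rule standing in for one enzyme sub-subclass.

    ``site_smarts`` locates applicable positions on a scaffold; ``edit``
    rewrites the scaffold at one site (the edited molecule may fall apart
    into several product fragments); ``cosubstrate``/``coproduct`` SMILES
    complete the equation so it balances.  ``zero_rfp`` marks templates
    whose product graph equals the substrate graph (stereo-only edits).
    """

    name: str
    ec: ECLabel
    site_smarts: str
    edit: EditFn
    cosubstrate: str | None = None
    coproduct: str | None = None
    zero_rfp: bool = False
    site_finder: SiteFn | None = None

    def sites(self, mol: Chem.Mol) -> list[tuple[int, ...]]:
        if self.site_finder is not None:
            return self.site_finder(mol)
        patt = Chem.MolFromSmarts(self.site_smarts)
        return [tuple(m) for m in mol.GetSubstructMatches(patt, uniquify=True)]

    def apply(self, scaffold: Chem.Mol, site: tuple[int, ...]) -> list[str]:
        """Product SMILES (one per fragment) from editing one site."""
        rw = Chem.RWMol(scaffold)
        edited = self.edit(rw, site)
        Chem.SanitizeMol(edited)
        frags = Chem.GetMolFrags(edited, asMols=True)
        return [Chem.MolToSmiles(f) for f in frags]


# ---------------------------------------------------------------------------
# edit rules

def _methylate_amine(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(site[0], c, Chem.BondType.SINGLE)
    return rw.GetMol()


def _aminate_alcohol(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    rw.GetAtomWithIdx(site[0]).SetAtomicNum(7)
    return rw.GetMol()


def _hydrolyse_ester(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    # site ends (..., ester O, alkyl C): cleave O-alkyl and give the alkyl
    # carbon a fresh hydroxyl.
    o_ester, c_alkyl = site[-2], site[-1]
    rw.RemoveBond(o_ester, c_alkyl)
    o_new = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(c_alkyl, o_new, Chem.BondType.SINGLE)
    return rw.GetMol()


def _phosphorylate_alcohol(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    o = site[0]
    p = rw.AddAtom(Chem.Atom(15))
    rw.AddBond(o, p, Chem.BondType.SINGLE)
    o_dbl = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(p, o_dbl, Chem.BondType.DOUBLE)
    for _ in range(2):
        oh = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(p, oh, Chem.BondType.SINGLE)
    return rw.GetMol()


def _decarboxylate(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    # site = (amine N, alpha C, carboxyl C, carbonyl O, hydroxyl O): drop
    # the whole carboxyl group (the CO2 leaves as the declared coproduct).
    for idx in sorted(site[2:], reverse=True):
        rw.RemoveAtom(idx)
    return rw.GetMol()


def _oxidise_secondary_alcohol(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    c, o = site[0], site[1]
    rw.GetBondBetweenAtoms(c, o).SetBondType(Chem.BondType.DOUBLE)
    return rw.GetMol()


def _invert_stereocentre(rw: Chem.RWMol, site: tuple[int, ...]) -> Chem.Mol:
    atom = rw.GetAtomWithIdx(site[0])
    flip = {
        Chem.ChiralType.CHI_TETRAHEDRAL_CW: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    }
    tag = atom.GetChiralTag()
    if tag not in flip:
        raise TemplateError("racemase site is not a tetrahedral stereocentre")
    atom.SetChiralTag(flip[tag])
    return rw.GetMol()


def _stereocentres(mol: Chem.Mol) -> list[tuple[int, ...]]:
    return [(idx,) for idx, _ in
            Chem.FindMolChiralCenters(mol, includeUnassigned=False)]


# ---------------------------------------------------------------------------
# default study conditions

#: Hand-curated scaffolds, all <= 12 heavy atoms so oracle hand-enumeration
#: stays feasible.  Name -> SMILES.
DEFAULT_SCAFFOLDS: Mapping[str, str] = {
    "ethanolamine": "NCCO",
    "3-amino-1-propanol": "NCCCO",
    "4-amino-1-butanol": "NCCCCO",
    "5-amino-1-pentanol": "NCCCCCO",
    "benzylamine": "NCc1ccccc1",
    "2-phenylethylamine": "NCCc1ccccc1",
    "2-aminopropan-1-ol": "CC(N)CO",
    "ethanol": "CCO",
    "1-propanol": "CCCO",
    "1-butanol": "CCCCO",
    "1-pentanol": "CCCCCO",
    "1-hexanol": "CCCCCCO",
    "3-methyl-1-butanol": "CC(C)CCO",
    "benzyl alcohol": "OCc1ccccc1",
    "propane-1,2-diol": "CC(O)CO",
    "propan-2-ol": "CC(C)O",
    "butan-2-ol": "CCC(C)O",
    "pentan-2-ol": "CCCC(C)O",
    "cyclopentanol": "OC1CCCC1",
    "cyclohexanol": "OC1CCCCC1",
    "1-phenylpropan-2-ol": "CC(O)Cc1ccccc1",
    "methyl acetate": "COC(C)=O",
    "ethyl acetate": "CCOC(C)=O",
    "methyl propanoate": "CCC(=O)OC",
    "ethyl propanoate": "CCOC(=O)CC",
    "propyl acetate": "CCCOC(C)=O",
    "butyl acetate": "CCCCOC(C)=O",
    "isopropyl acetate": "CC(C)OC(C)=O",
    "methyl benzoate": "COC(=O)c1ccccc1",
    "alanine": "CC(N)C(=O)O",
    "2-aminobutanoic acid": "CCC(N)C(=O)O",
    "norvaline": "CCCC(N)C(=O)O",
    "serine": "NC(CO)C(=O)O",
    "threonine": "CC(O)C(N)C(=O)O",
    "valine": "CC(C)C(N)C(=O)O",
    "leucine": "CC(C)CC(N)C(=O)O",
    "phenylalanine": "NC(Cc1ccccc1)C(=O)O",
}

#: Stereo-defined scaffolds for the racemase template only.
RACEMASE_SCAFFOLDS: Mapping[str, str] = {
    "L-alanine": "C[C@@H](N)C(=O)O",
    "L-serine": "N[C@@H](CO)C(=O)O",
    "L-valine": "CC(C)[C@@H](N)C(=O)O",
    "L-leucine": "CC(C)C[C@@H](N)C(=O)O",
    "L-phenylalanine": "N[C@@H](Cc1ccccc1)C(=O)O",
}

N_METHYLATION = TransformationTemplate(
    name="amine N-methylation",
    ec=ECLabel((2, 1, 1)),
    site_smarts="[NX3;H2][CX4;H2]",   # primary amines on a methylene carbon
    edit=_methylate_amine,
    cosubstrate="CO",   # methyl donor
    coproduct="O",
)

AMINATION = TransformationTemplate(
    name="alcohol amination",
    ec=ECLabel((2, 6, 1)),
    # primary alcohols on an unbranched aliphatic chain
    site_smarts="[OX2H][CX4;H2][CX4H2,CX4H3]",
    edit=_aminate_alcohol,
    cosubstrate="N",
    coproduct="O",
)

ESTER_HYDROLYSIS = TransformationTemplate(
    name="ester hydrolysis",
    ec=ECLabel((3, 1, 1)),
    # esters of unbranched acyl and alkyl partners
    site_smarts="[CX4H3,CX4H2][CX3](=[OX1])[OX2][CX4H2,CX4H3]",
    edit=_hydrolyse_ester,
    cosubstrate="O",
)

PHOSPHOTRANSFER = TransformationTemplate(
    name="alcohol phosphotransfer",
    ec=ECLabel((2, 7, 1)),
    site_smarts="[OX2H][CX4;H2][CX4H2,CX4H3]",
    edit=_phosphorylate_alcohol,
    cosubstrate="COP(=O)(O)OP(=O)(O)O",  # pyrophosphate-type donor
    coproduct="COP(=O)(O)O",
)

DECARBOXYLATION = TransformationTemplate(
    name="amino-acid decarboxylation",
    ec=ECLabel((4, 1, 1)),
    site_smarts="[NX3;H2][CX4;H1][CX3](=[OX1])[OX2H]",
    edit=_decarboxylate,
    coproduct="O=C=O",
)

ALCOHOL_OXIDATION = TransformationTemplate(
    name="secondary-alcohol oxidation",
    ec=ECLabel((1, 1, 1)),
    # secondary alcohols flanked by unbranched carbons
    site_smarts="[CX4;H1]([OX2H])([CX4H2,CX4H3])[CX4H2,CX4H3]",
    edit=_oxidise_secondary_alcohol,
    cosubstrate="C=O",   # hydride acceptor
    coproduct="CO",
)

RACEMISATION = TransformationTemplate(
    name="amino-acid racemisation",
    ec=ECLabel((5, 1, 1)),
    site_smarts="",
    edit=_invert_stereocentre,
    zero_rfp=True,
    site_finder=_stereocentres,
)

DEFAULT_TEMPLATES: tuple[TransformationTemplate, ...] = (
    ALCOHOL_OXIDATION,
    N_METHYLATION,
    AMINATION,
    PHOSPHOTRANSFER,
    ESTER_HYDROLYSIS,
    DECARBOXYLATION,
)

#: Templates whose edit signatures share no fingerprint coordinate at path
#: length 3 (methylation/amination deliberately overlap, so amination and
#: oxidation are left out): every between-class distance strictly exceeds
#: every within-class one on sets generated from these.
DISJOINT_TEMPLATES: tuple[TransformationTemplate, ...] = (
    N_METHYLATION,
    PHOSPHOTRANSFER,
    ESTER_HYDROLYSIS,
    DECARBOXYLATION,
)


@dataclass
class SyntheticSet:
    """A generated corpus: compound table (id -> SMILES) plus reactions."""

    compounds: dict[str, str]
    reactions: list[Reaction]

    def compound_graphs(self) -> dict[str, MoleculeGraph]:
        from .chemgraph import parse_molecule
        return {cid: parse_molecule(smi, "smiles", id=cid)
                for cid, smi in self.compounds.items()}

    def write(self, out_dir) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cpath, rpath = out / "compounds.tsv", out / "reactions.tsv"
        write_compounds_tsv(cpath, self.compounds)
        write_reactions_tsv(rpath, self.reactions)
        return cpath, rpath


class _CompoundRegistry:
    """Canonical-SMILES-deduplicated compound table with sequential ids."""

    def __init__(self, prefix: str = "M"):
        self.prefix = prefix
        self.by_canon: dict[str, str] = {}
        self.table: dict[str, str] = {}

    def add(self, smiles: str) -> str:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise TemplateError(f"registry got unparseable SMILES {smiles!r}")
        canon = Chem.MolToSmiles(mol)
        if canon not in self.by_canon:
            cid = f"{self.prefix}{len(self.by_canon) + 1:04d}"
            self.by_canon[canon] = cid
            self.table[cid] = canon
        return self.by_canon[canon]


def generate_reaction_set(
    templates: Sequence[TransformationTemplate] | None = None,
    scaffolds: Mapping[str, str] | None = None,
    n_per_template: int = 5,
    seed: int = 0,
    *,
    include_zero_rfp: bool = False,
    racemase_scaffolds: Mapping[str, str] | None = None,
) -> SyntheticSet:
    """Emit a labelled reaction set from templates applied to scaffolds.

    For each template, ``n_per_template`` distinct (scaffold, site)
    combinations are drawn without replacement by a ``seed``-fixed RNG.
    Every emitted reaction is elementally balanced, fully structured and
    EC-labelled (it passes dataset-filter categories 1-5).  Templates whose
    edits are invisible to stereo-agnostic fingerprints (``zero_rfp``) are
    only used when ``include_zero_rfp`` is set; the default racemisation
    template then draws from its own stereo-defined scaffold pool.
    """
    if n_per_template < 1:
        raise TemplateError("n_per_template must be >= 1")
    chosen_templates = list(templates if templates is not None else DEFAULT_TEMPLATES)
    if include_zero_rfp and all(not t.zero_rfp for t in chosen_templates):
        chosen_templates.append(RACEMISATION)
    if not include_zero_rfp:
        blocked = [t.name for t in chosen_templates if t.zero_rfp]
        if blocked:
            raise TemplateError(
                f"zero-RFP templates {blocked} require include_zero_rfp=True")
    scaffolds = dict(scaffolds if scaffolds is not None else DEFAULT_SCAFFOLDS)
    racemase_pool = dict(racemase_scaffolds if racemase_scaffolds is not None
                         else RACEMASE_SCAFFOLDS)

    rng = random.Random(seed)
    registry = _CompoundRegistry()
    reactions: list[Reaction] = []
    serial = 0

    for template in chosen_templates:
        pool = racemase_pool if template.zero_rfp else scaffolds
        combos: list[tuple[str, str, tuple[int, ...]]] = []
        mols: dict[str, Chem.Mol] = {}
        for name, smi in pool.items():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise TemplateError(f"scaffold {name!r} has bad SMILES {smi!r}")
            sites = template.sites(mol)
            if sites:
                mols[name] = mol
                combos.extend((name, smi, site) for site in sites)
        if not combos:
            raise TemplateError(
                f"template {template.name!r} applies to no scaffold")
        if len(combos) < n_per_template:
            raise TemplateError(
                f"template {template.name!r} has only {len(combos)} "
                f"(scaffold, site) combinations, need {n_per_template}")
        for name, smi, site in rng.sample(combos, n_per_template):
            substrate_id = registry.add(smi)
            reactants: list[tuple[int, str]] = [(1, substrate_id)]
            if template.cosubstrate:
                reactants.append((1, registry.add(template.cosubstrate)))
            products = [(1, registry.add(p))
                        for p in template.apply(mols[name], site)]
            if template.coproduct:
                products.append((1, registry.add(template.coproduct)))
            serial += 1
            reactions.append(Reaction(
                id=f"X{serial:04d}",
                reactants=tuple(reactants),
                products=tuple(products),
                ec=template.ec,
            ))
    return SyntheticSet(registry.table, reactions)
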