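"""Heavy-atom molecular graphs and counted linear-fragment enumeration.

A molecule is reduced to its heavy-atom graph (hydrogens implicit, stereo
discarded) and described by the multiset of its *linear fragments*: simple
paths of 0..``max_len`` bonds written as alternating atom and bond symbols,
e.g. ``C-C=O`` or ``c:c:c``.  Atom symbols are element symbols, lower-cased
on aromatic atoms; bond symbols are ``-``, ``=``, ``#``, ``:`` for single,
double, triple and aromatic bonds.  A fragment string is *canonical* when it
equals the lexicographic minimum of its forward and reversed spellings.

Two counting conventions are supported:

``directed=False`` (default)
    each simple path and its reverse count as one occurrence of the
    canonical fragment;
``directed=True``
    both orientations are counted, so every fragment of length >= 1 carries
    twice the deduplicated count.  This is the convention on which the
    original method's published reaction distances live (see docs/methods.md).

Single atoms (length-0 fragments) are counted once per atom under either
convention.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    FragmentLengthError,
    FragmentSyntaxError,
    RxndiffError,
    StructureParseError,
)

# RDKit warns loudly on perfectly usable records; errors surface as None.
RDLogger.DisableLog("rdApp.*")

#: Largest supported path length, in bonds (7 atoms).
MAX_PATH_LENGTH = 6

BOND_SYMBOLS: Mapping[Chem.BondType, str] = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

_VALID_BONDS = frozenset("-=#:")

# atom token: wildcard, or element symbol (lower-cased when aromatic),
# optionally followed by a ^-prefixed formal charge.
_ATOM_TOKEN = re.compile(r"\*|[A-Za-z][a-z]?(?:\^[+-]\d+)?")


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, aromatic flag, formal charge."""

    element: str
    aromatic: bool = False
    charge: int = 0
    wildcard: bool = False

    def symbol(self, with_charge: bool = False) -> str:
        """Fragment-string symbol under the configured dialect."""
        if self.wildcard:
            return "*"
        s = self.element.lower() if self.aromatic else self.element
        if with_charge and self.charge:
            s += f"^{self.charge:+d}"
        return s


@dataclass(frozen=True)
class MoleculeGraph:
    """Hydrogen-suppressed molecular graph.

    ``bonds`` holds ``(i, j, order)`` triples with ``order`` one of
    ``- = # :``.  At most one bond per unordered atom pair; aromatic bonds
    may only join aromatic-flagged atoms.
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, str], ...]
    id: str | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for atom in self.atoms:
            if atom.element == "H":
                raise RxndiffError("hydrogens must be implicit in MoleculeGraph")
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise RxndiffError(f"bond ({i},{j}) has invalid endpoints")
            pair = frozenset((i, j))
            if pair in seen:
                raise RxndiffError(f"duplicate bond between atoms {i} and {j}")
            seen.add(pair)
            if order not in _VALID_BONDS:
                raise RxndiffError(f"unknown bond symbol {order!r}")
            if order == ":" and not (self.atoms[i].aromatic and self.atoms[j].aromatic):
                raise RxndiffError("aromatic bond joining non-aromatic atoms")

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_wildcard(self) -> bool:
        """True when the record contained R-group / wildcard atoms."""
        return any(a.wildcard for a in self.atoms)

    def element_counts(self) -> Counter:
        """Multiset of heavy-atom element symbols (wildcards as ``*``)."""
        return Counter("*" if a.wildcard else a.element for a in self.atoms)

    def adjacency(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


class Fragment(str):
    """A canonical linear-fragment string.

    Behaves as a plain ``str`` whose value is the lexicographic minimum of
    the forward and reversed spellings; ``length`` is the bond count.
    """

    def __new__(cls, text: str) -> "Fragment":
        atoms, bonds = _tokenize(text)
        canon = _canonical_from_tokens(_interleave(atoms, bonds))
        obj = super().__new__(cls, canon)
        obj._length = len(bonds)
        return obj

    @property
    def length(self) -> int:
        return self._length


def _tokenize(text: str) -> tuple[list[str], list[str]]:
    """Split a fragment string into atom and bond token lists."""
    atoms: list[str] = []
    bonds: list[str] = []
    pos = 0
    expect_atom = True
    while pos < len(text):
        if expect_atom:
            m = _ATOM_TOKEN.match(text, pos)
            if not m:
                raise FragmentSyntaxError(
                    f"expected atom symbol at position {pos} in {text!r}")
            atoms.append(m.group())
            pos = m.end()
        else:
            if text[pos] not in _VALID_BONDS:
                raise FragmentSyntaxError(
                    f"expected bond symbol at position {pos} in {text!r}")
            bonds.append(text[pos])
            pos += 1
        expect_atom = not expect_atom
    if not atoms or expect_atom:
        raise FragmentSyntaxError(f"fragment {text!r} must end on an atom symbol")
    return atoms, bonds


def _interleave(atoms: list[str], bonds: list[str]) -> list[str]:
    tokens = [atoms[0]]
    for bond, atom in zip(bonds, atoms[1:]):
        tokens.append(bond)
        tokens.append(atom)
    return tokens


def _canonical_from_tokens(tokens: list[str]) -> str:
    forward = "".join(tokens)
    backward = "".join(reversed(tokens))
    return forward if forward <= backward else backward


def fragment_length(fragment: str) -> int:
    """Number of bonds in a fragment string."""
    return Fragment(fragment).length


def parse_molecule(text: str, fmt: str = "smiles", id: str | None = None) -> MoleculeGraph:
    """Parse a structure record into a :class:`MoleculeGraph`.

    Hydrogens are suppressed, aromaticity is perceived (kekulized input is
    re-aromatized), and stereochemical annotations are discarded.  Records
    containing wildcard/R-group atoms parse into a flagged graph rather than
    raising; downstream dataset filters exclude them.
    """
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt in ("molfile", "mol", "sdf"):
        mol = Chem.MolFromMolBlock(text, removeHs=True)
    else:
        raise RxndiffError(f"unknown structure format {fmt!r}")
    if mol is None:
        raise StructureParseError(text, fmt)
    return from_rdkit(mol, id=id)


def from_rdkit(mol: Chem.Mol, id: str | None = None) -> MoleculeGraph:
    """Convert an RDKit molecule (already sanitized) to a MoleculeGraph."""
    mol = Chem.RemoveHs(mol)
    atoms = []
    for a in mol.GetAtoms():
        wildcard = a.GetAtomicNum() == 0
        atoms.append(Atom(
            element="*" if wildcard else a.GetSymbol(),
            aromatic=a.GetIsAromatic(),
            charge=a.GetFormalCharge(),
            wildcard=wildcard,
        ))
    bonds = []
    for b in mol.GetBonds():
        order = BOND_SYMBOLS.get(b.GetBondType())
        if order is None:
            raise StructureParseError(
                Chem.MolToSmiles(mol), "rdkit", f"unsupported bond type {b.GetBondType()}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = id
    if name is None and mol.HasProp("_Name") and mol.GetProp("_Name"):
        name = mol.GetProp("_Name")
    return MoleculeGraph(atoms=tuple(atoms), bonds=tuple(bonds), id=name)


def enumerate_linear_fragments(
    mol: MoleculeGraph,
    max_len: int,
    *,
    directed: bool = False,
    with_charge: bool = False,
) -> dict[str, int]:
    """Count every simple path of 0..``max_len`` bonds in the graph.

    Returns a sparse ``{canonical fragment: count}`` map.  Length-0
    fragments are the single heavy atoms.  With ``directed=False`` a path
    and its reverse count once; with ``directed=True`` both orientations
    count, doubling every length >= 1 entry.
    """
    if not 0 <= max_len <= MAX_PATH_LENGTH:
        raise FragmentLengthError(
            f"max_len must be in 0..{MAX_PATH_LENGTH}, got {max_len}")

    symbols = [a.symbol(with_charge) for a in mol.atoms]
    counts: Counter = Counter()
    for s in symbols:
        counts[s] += 1
    if max_len == 0 or mol.num_atoms == 0:
        return dict(counts)

    adj = mol.adjacency()
    # Deterministic neighbour order keeps traversal reproducible (counts are
    # order-independent anyway).
    for nbrs in adj:
        nbrs.sort()

    path = [0]
    tokens = [""]

    def extend(start: int) -> None:
        last = path[-1]
        for j, order in adj[last]:
            if j in path:
                continue
            path.append(j)
            tokens.append(order)
            tokens.append(symbols[j])
            if directed or start < j:
                counts[_canonical_from_tokens(tokens)] += 1
            if len(path) <= max_len:
                extend(start)
            path.pop()
            tokens.pop()
            tokens.pop()

    for i in range(mol.num_atoms):
        path[:] = [i]
        tokens[:] = [symbols[i]]
        extend(i)
    return dict(counts)


def write_fragment_tsv(path, counts: Mapping[str, int], *, max_len: int,
                       directed: bool = False, with_charge: bool = False) -> None:
    """Serialize a fragment map as ``fragment<TAB>count`` with a dialect header."""
    from . import __version__
    lines = [
        f"# rxndiff {__version__} fragment table",
        f"# max_len={max_len} directed={directed} with_charge={with_charge}",
        "fragment\tcount",
    ]
    for frag in sorted(counts):
        lines.append(f"{frag}\t{counts[frag]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
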