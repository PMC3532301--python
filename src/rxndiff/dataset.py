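"""Reaction data model, file readers, and the six-case exclusion filter.

Training corpora arrive as two plain-text tables: a compound table mapping
compound ids to structures (TSV ``id<TAB>SMILES`` or an SDF), and a reaction
table of KEGG-style equations with optional EC labels
(``id<TAB>equation<TAB>EC``).  Before fingerprinting, a corpus passes a
six-case exclusion filter that removes reactions the method cannot score:

1. elementally unbalanced equations (heavy-atom element counts, weighted by
   stoichiometric coefficients, differ between the two sides — a proxy for
   equations with missing molecules);
2. reactions involving glycan compounds (id namespace prefix ``G``);
3. reactions without an EC label;
4. reactions citing a compound with no structure record;
5. reactions with wildcard/R-group atoms or symbolic (polymer-style)
   coefficients;
6. reactions whose difference fingerprint is exactly zero at the working
   path length (racemases/epimerases and other stereo-only transformations).

Categories overlap; they are tested in the order above and the first match
is recorded.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .chemgraph import MoleculeGraph, from_rdkit, parse_molecule
from .errors import (
    ECLabelError,
    EquationParseError,
    RxndiffError,
    UnknownCompoundError,
)
from .fingerprint import reaction_difference_fingerprint

Coefficient = Union[int, str]  # str only for symbolic (polymer) coefficients

_ARROW = re.compile(r"<\s*=\s*>")
_INT = re.compile(r"\d+$")


@dataclass(frozen=True, order=True)
class ECLabel:
    """A dotted EC hierarchy prefix: 1-4 defined components.

    Trailing ``-`` placeholders in the input are accepted and dropped; a
    defined field may not follow a placeholder.  Ordering is lexicographic
    on the component tuple, which gives the deterministic tie-break used by
    the classifier.
    """

    components: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 4:
            raise ECLabelError(f"EC label needs 1-4 components, got {self.components}")
        if any(c < 1 for c in self.components):
            raise ECLabelError(f"EC components must be positive: {self.components}")
        if not 1 <= self.components[0] <= 6:
            raise ECLabelError(f"EC main class must be 1..6, got {self.components[0]}")

    @classmethod
    def parse(cls, text: str) -> "ECLabel":
        text = text.strip()
        if text.upper().startswith("EC"):
            text = text[2:].strip()
        fields = text.split(".")
        comps: list[int] = []
        seen_placeholder = False
        for f in fields:
            f = f.strip()
            if f in ("-", ""):
                seen_placeholder = True
                continue
            if seen_placeholder:
                raise ECLabelError(f"defined field after placeholder in {text!r}")
            if not _INT.match(f):
                raise ECLabelError(f"non-integer EC component {f!r} in {text!r}")
            comps.append(int(f))
        if not comps:
            raise ECLabelError(f"no defined components in EC label {text!r}")
        return cls(tuple(comps))

    @property
    def level(self) -> int:
        return len(self.components)

    @property
    def main_class(self) -> int:
        return self.components[0]

    def truncate(self, level: int) -> "ECLabel":
        return ec_truncate(self, level)

    def __str__(self) -> str:
        return ".".join(str(c) for c in self.components)


def ec_truncate(ec: ECLabel, level: int) -> ECLabel:
    """First ``level`` components of an EC label.

    Raises when the label has fewer defined components than requested — the
    reaction is then unusable at that scoring level.
    """
    if not 1 <= level <= 4:
        raise ECLabelError(f"EC level must be 1..4, got {level}")
    if ec.level < level:
        raise ECLabelError(
            f"EC label {ec} has only {ec.level} defined components, need {level}")
    return ECLabel(ec.components[:level])


@dataclass(frozen=True)
class Reaction:
    """One reaction: id, stoichiometry-weighted sides, optional EC label.

    Coefficients are positive integers; a symbolic coefficient (polymer
    notation such as ``n`` or ``(n+1)``) may be carried as a string so the
    dataset filter can classify the reaction, but no fingerprint operation
    accepts it.
    """

    id: str
    reactants: tuple[tuple[Coefficient, str], ...]
    products: tuple[tuple[Coefficient, str], ...]
    ec: ECLabel | None = None

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise RxndiffError(f"reaction {self.id}: both sides must be non-empty")
        for coef, cid in (*self.reactants, *self.products):
            if isinstance(coef, int) and coef < 1:
                raise RxndiffError(
                    f"reaction {self.id}: coefficient {coef} for {cid} must be >= 1")

    @property
    def has_symbolic_coefficients(self) -> bool:
        return any(isinstance(c, str)
                   for c, _ in (*self.reactants, *self.products))

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(cid for _, cid in (*self.reactants, *self.products))

    def reversed(self) -> "Reaction":
        return Reaction(self.id, self.products, self.reactants, self.ec)

    @property
    def equation(self) -> str:
        return format_equation(self.reactants, self.products)


def _format_side(side: Iterable[tuple[Coefficient, str]]) -> str:
    terms = []
    for coef, cid in side:
        terms.append(cid if coef == 1 else f"{coef} {cid}")
    return " + ".join(terms)


def format_equation(reactants, products) -> str:
    return f"{_format_side(reactants)} <=> {_format_side(products)}"


def _split_terms(text: str) -> list[str]:
    """Split on ``+`` separators, ignoring any inside parentheses
    (polymer coefficients like ``(n+1)``)."""
    parts: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif ch == "+" and depth == 0:
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return parts


def _parse_side(text: str, offset: int, allow_symbolic: bool,
                full: str) -> tuple[tuple[Coefficient, str], ...]:
    terms: list[tuple[Coefficient, str]] = []
    pos = offset
    for raw in _split_terms(text):
        term = raw.strip()
        if not term:
            raise EquationParseError(full, pos, "empty term")
        parts = term.split(None, 1)
        coef: Coefficient
        if len(parts) == 2 and re.fullmatch(r"\d+", parts[0]):
            coef, cid = int(parts[0]), parts[1].strip()
            if coef < 1:
                raise EquationParseError(full, pos, f"coefficient {coef} must be >= 1")
        elif len(parts) == 2 and re.fullmatch(r"\(?[0-9a-zA-Z+\-*]*[a-zA-Z][0-9a-zA-Z+\-*]*\)?",
                                              parts[0]):
            # symbolic coefficient such as "n" or "(n+1)"
            if not allow_symbolic:
                raise EquationParseError(
                    full, pos, f"symbolic coefficient {parts[0]!r}")
            coef, cid = parts[0], parts[1].strip()
        else:
            coef, cid = 1, term
        if not cid:
            raise EquationParseError(full, pos, "missing compound id")
        terms.append((coef, cid))
        pos += len(raw) + 1
    if not terms:
        raise EquationParseError(full, offset, "empty reaction side")
    return tuple(terms)


def parse_equation(
    text: str,
    *,
    allow_symbolic: bool = False,
) -> tuple[tuple[tuple[Coefficient, str], ...], tuple[tuple[Coefficient, str], ...]]:
    """Split a KEGG-style equation into (reactants, products).

    Terms are split on ``+``; a leading integer is the coefficient
    (default 1); compound ids are preserved verbatim.  Exactly one
    reversible-arrow token (``<=>``, whitespace-tolerant) must be present.
    Symbolic coefficients raise unless ``allow_symbolic`` is set (the loader
    sets it so polymer reactions reach the dataset filter).
    """
    arrows = list(_ARROW.finditer(text))
    if len(arrows) != 1:
        raise EquationParseError(
            text, 0, f"expected exactly one '<=>' arrow, found {len(arrows)}")
    arrow = arrows[0]
    left, right = text[:arrow.start()], text[arrow.end():]
    if not left.strip():
        raise EquationParseError(text, 0, "empty reactant side")
    if not right.strip():
        raise EquationParseError(text, arrow.end(), "empty product side")
    return (_parse_side(left, 0, allow_symbolic, text),
            _parse_side(right, arrow.end(), allow_symbolic, text))


# ---------------------------------------------------------------------------
# readers / writers

def read_compounds_tsv(path) -> dict[str, MoleculeGraph | None]:
    """Read a TSV compound table (``id<TAB>SMILES``).

    An empty or ``-`` structure field declares the compound as known but
    structureless (dataset-filter category 4); the id is still resolvable.
    Lines starting with ``#`` and a header line ``id<TAB>smiles`` are skipped.
    """
    table: dict[str, MoleculeGraph | None] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        cid = parts[0].strip()
        if cid.lower() in ("id", "compound", "compound_id"):
            continue
        smiles = parts[1].strip() if len(parts) > 1 else ""
        if not smiles or smiles == "-":
            table[cid] = None
        else:
            table[cid] = parse_molecule(smiles, "smiles", id=cid)
    return table


def read_compounds_sdf(path, id_field: str = "_Name") -> dict[str, MoleculeGraph | None]:
    """Read compounds from an SDF; ids from ``id_field`` (default mol title)."""
    from rdkit import Chem

    table: dict[str, MoleculeGraph | None] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise RxndiffError(f"unparseable SDF record #{i} in {path}")
        if id_field == "_Name":
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        else:
            cid = mol.GetProp(id_field) if mol.HasProp(id_field) else ""
        if not cid:
            raise RxndiffError(f"SDF record #{i} in {path} has no id field {id_field!r}")
        table[cid] = from_rdkit(mol, id=cid)
    return table


def write_compounds_tsv(path, compounds: Mapping[str, str]) -> None:
    """Write a compound table from an ``id -> SMILES`` mapping."""
    lines = ["id\tsmiles"]
    for cid in compounds:
        lines.append(f"{cid}\t{compounds[cid]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reactions_tsv(path) -> list[Reaction]:
    """Read a reaction table (``id<TAB>equation[<TAB>EC]``).

    Symbolic coefficients are tolerated here (they are filter category 5).
    Multiple whitespace-separated ECs in the third column keep the first.
    """
    reactions: list[Reaction] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        rid = parts[0].strip()
        if rid.lower() in ("id", "reaction", "reaction_id"):
            continue
        if len(parts) < 2 or not parts[1].strip():
            raise RxndiffError(f"{path}:{lineno}: missing equation for {rid!r}")
        reactants, products = parse_equation(parts[1].strip(), allow_symbolic=True)
        ec = None
        if len(parts) > 2 and parts[2].strip() and parts[2].strip() != "-":
            ec = ECLabel.parse(parts[2].split()[0])
        reactions.append(Reaction(rid, reactants, products, ec))
    return reactions


def write_reactions_tsv(path, reactions: Sequence[Reaction]) -> None:
    lines = ["id\tequation\tec"]
    for r in reactions:
        lines.append(f"{r.id}\t{r.equation}\t{r.ec if r.ec is not None else '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def reaction_from_smiles(rxn_smiles: str, id: str,
                         ec: str | ECLabel | None = None,
                         compound_prefix: str = "C",
                         ) -> tuple[Reaction, dict[str, MoleculeGraph]]:
    """Build a Reaction plus compound table from reaction SMILES ``A.B>>C.D``.

    Identical structures (by canonical SMILES) share one compound id;
    repeats of a structure on one side become a stoichiometric coefficient.
    """
    from rdkit import Chem

    parts = rxn_smiles.split(">>")
    if len(parts) != 2:
        raise RxndiffError(f"reaction SMILES needs exactly one '>>': {rxn_smiles!r}")
    table: dict[str, MoleculeGraph] = {}
    canon_to_id: dict[str, str] = {}

    def side(text: str) -> tuple[tuple[int, str], ...]:
        counts: Counter = Counter()
        order: list[str] = []
        for smi in filter(None, (s.strip() for s in text.split("."))):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise RxndiffError(f"bad component {smi!r} in reaction SMILES")
            canon = Chem.MolToSmiles(mol)
            if canon not in canon_to_id:
                cid = f"{compound_prefix}{len(canon_to_id) + 1:04d}"
                canon_to_id[canon] = cid
                table[cid] = from_rdkit(mol, id=cid)
            cid = canon_to_id[canon]
            if cid not in order:
                order.append(cid)
            counts[cid] += 1
        return tuple((counts[cid], cid) for cid in order)

    reactants = side(parts[0])
    products = side(parts[1])
    label = ECLabel.parse(ec) if isinstance(ec, str) else ec
    return Reaction(id, reactants, products, label), table


# ---------------------------------------------------------------------------
# the six-case exclusion filter

CATEGORY_NAMES: Mapping[int, str] = {
    1: "elementally unbalanced equation",
    2: "glycan participant",
    3: "missing EC label",
    4: "compound without structure",
    5: "wildcard atoms or symbolic coefficients",
    6: "zero reaction difference fingerprint",
}


@dataclass(frozen=True)
class Disposition:
    reaction_id: str
    category: int | None  # None = kept
    message: str = ""

    @property
    def kept(self) -> bool:
        return self.category is None


@dataclass(frozen=True)
class FilterReport:
    """Per-reaction dispositions of one filter run.

    Every input reaction appears exactly once; categories are tested in
    declared order and the first match is recorded.
    """

    dispositions: tuple[Disposition, ...]
    max_len: int

    @property
    def kept_ids(self) -> tuple[str, ...]:
        return tuple(d.reaction_id for d in self.dispositions if d.kept)

    @property
    def category_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in CATEGORY_NAMES}
        for d in self.dispositions:
            if d.category is not None:
                counts[d.category] += 1
        return counts

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def n_total(self) -> int:
        return len(self.dispositions)

    def apply(self, reactions: Sequence[Reaction]) -> list[Reaction]:
        keep = set(self.kept_ids)
        return [r for r in reactions if r.id in keep]

    def summary(self) -> str:
        lines = [
            f"filter summary (max_len={self.max_len}; categories tested in order 1-6,"
            " first match recorded)",
            f"  input reactions : {self.n_total}",
            f"  kept            : {self.n_kept}",
        ]
        counts = self.category_counts
        for cat, name in CATEGORY_NAMES.items():
            lines.append(f"  excluded cat {cat} : {counts[cat]:<5d} {name}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from . import __version__
        lines = [
            f"# rxndiff {__version__} filter report",
            f"# max_len={self.max_len} category_order=1,2,3,4,5,6 (first match recorded)",
            "reaction\tdisposition\tcategory\tmessage",
        ]
        for d in self.dispositions:
            if d.kept:
                lines.append(f"{d.reaction_id}\tkept\t-\t")
            else:
                lines.append(f"{d.reaction_id}\texcluded\t{d.category}\t{d.message}")
        Path(path).write_text("\n".join(lines) + "\n")


def _weighted_elements(side, compounds) -> Counter | None:
    """Coefficient-weighted heavy-atom element counts; None if indeterminate."""
    total: Counter = Counter()
    for coef, cid in side:
        mol = compounds.get(cid)
        if mol is None or mol.has_wildcard or not isinstance(coef, int):
            return None
        for elem, n in mol.element_counts().items():
            total[elem] += coef * n
    return total


def filter_dataset(
    reactions: Sequence[Reaction],
    compounds: Mapping[str, MoleculeGraph | None],
    max_len: int,
    *,
    glycan_prefixes: Sequence[str] = ("G",),
    glycan_overrides: Sequence[str] = (),
    directed: bool = False,
    with_charge: bool = False,
) -> FilterReport:
    """Apply the six exclusion cases to a reaction set.

    ``glycan_overrides`` lists ids that match a glycan prefix but should not
    count as glycans.  An id absent from ``compounds`` altogether raises
    :class:`UnknownCompoundError` (data-integrity failure) — distinct from a
    declared-but-structureless compound, which is category 4.
    """
    overrides = set(glycan_overrides)
    dispositions: list[Disposition] = []
    for rxn in reactions:
        for cid in rxn.compound_ids:
            if cid not in compounds:
                raise UnknownCompoundError(cid)
        dispositions.append(
            _disposition(rxn, compounds, max_len, tuple(glycan_prefixes),
                         overrides, directed, with_charge))
    return FilterReport(tuple(dispositions), max_len)


def _disposition(rxn, compounds, max_len, glycan_prefixes, overrides,
                 directed, with_charge) -> Disposition:
    # 1: unbalanced (only decidable when every structure is known and exact)
    left = _weighted_elements(rxn.reactants, compounds)
    right = _weighted_elements(rxn.products, compounds)
    if left is not None and right is not None and left != right:
        diff = {e: left.get(e, 0) - right.get(e, 0)
                for e in set(left) | set(right)
                if left.get(e, 0) != right.get(e, 0)}
        return Disposition(rxn.id, 1, f"element imbalance {diff}")
    # 2: glycans
    for cid in rxn.compound_ids:
        if cid in overrides:
            continue
        if any(cid.startswith(p) for p in glycan_prefixes):
            return Disposition(rxn.id, 2, f"glycan compound {cid}")
    # 3: no EC
    if rxn.ec is None:
        return Disposition(rxn.id, 3, "no EC assignment")
    # 4: declared-missing structures
    for cid in rxn.compound_ids:
        if compounds[cid] is None:
            return Disposition(rxn.id, 4, f"no structure for {cid}")
    # 5: wildcard atoms / symbolic coefficients
    for cid in rxn.compound_ids:
        mol = compounds[cid]
        if mol is not None and mol.has_wildcard:
            return Disposition(rxn.id, 5, f"wildcard atoms in {cid}")
    if rxn.has_symbolic_coefficients:
        return Disposition(rxn.id, 5, "symbolic (polymer) coefficients")
    # 6: zero difference fingerprint at the working length
    rfp = reaction_difference_fingerprint(
        rxn, compounds, max_len, directed=directed, with_charge=with_charge)
    if rfp.is_zero:
        return Disposition(rxn.id, 6, f"zero difference fingerprint at max_len={max_len}")
    return Disposition(rxn.id, None)
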