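"""Fingerprint algebra: molecular fingerprints, reaction difference
fingerprints, and the Euclidean reaction distance.

The molecular fingerprint (MFP) of a molecule is the sparse integer vector
of its counted linear fragments.  The reaction difference fingerprint (RFP)
of a reaction is the stoichiometry-weighted reactant MFP sum minus the
product MFP sum:

    RFP = sum_r coef_r * MFP_r  -  sum_p coef_p * MFP_p

Exact-zero coordinates are dropped, so an RFP stores only the bond-pattern
change of the transformation.  Two reactions are compared by the Euclidean
norm of the difference of their RFPs, computed exactly on integers inside
the square root.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

from .chemgraph import MoleculeGraph, enumerate_linear_fragments
from .errors import (
    CoefficientError,
    DialectMismatchError,
    MissingStructureError,
    UnknownCompoundError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .dataset import Reaction


@dataclass(frozen=True)
class MolecularFingerprint:
    """Sparse map canonical fragment -> positive occurrence count."""

    entries: Mapping[str, int]
    max_len: int
    directed: bool = False

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("molecular fingerprint counts must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, fragment: str) -> int:
        return self.entries.get(fragment, 0)


@dataclass(frozen=True)
class ReactionDifferenceFingerprint:
    """Sparse map canonical fragment -> signed count difference."""

    entries: Mapping[str, int]
    max_len: int
    directed: bool = False

    def __post_init__(self) -> None:
        if any(v == 0 for v in self.entries.values()):
            raise ValueError("zero entries must be dropped from an RFP")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, fragment: str) -> int:
        return self.entries.get(fragment, 0)

    @property
    def is_zero(self) -> bool:
        return not self.entries

    def __neg__(self) -> "ReactionDifferenceFingerprint":
        return ReactionDifferenceFingerprint(
            {k: -v for k, v in self.entries.items()}, self.max_len, self.directed)

    def norm(self) -> float:
        """Euclidean norm (distance to the zero fingerprint)."""
        return math.sqrt(sum(v * v for v in self.entries.values()))


def molecular_fingerprint(
    mol: MoleculeGraph,
    max_len: int,
    *,
    directed: bool = False,
    with_charge: bool = False,
) -> MolecularFingerprint:
    """Counted linear fragments of ``mol`` wrapped with dialect metadata."""
    counts = enumerate_linear_fragments(
        mol, max_len, directed=directed, with_charge=with_charge)
    return MolecularFingerprint(counts, max_len, directed)


def _weighted_side(
    side: Iterable[tuple[int, str]],
    compounds: Mapping[str, MoleculeGraph | None],
    max_len: int,
    directed: bool,
    with_charge: bool,
    sign: int,
    acc: dict[str, int],
) -> None:
    for coef, cid in side:
        if not isinstance(coef, int) or isinstance(coef, bool):
            raise CoefficientError(
                f"stoichiometric coefficient {coef!r} for {cid} is not an integer")
        if coef < 1:
            raise CoefficientError(
                f"stoichiometric coefficient {coef} for {cid} must be positive")
        if cid not in compounds:
            raise UnknownCompoundError(cid)
        mol = compounds[cid]
        if mol is None:
            raise MissingStructureError(cid)
        counts = enumerate_linear_fragments(
            mol, max_len, directed=directed, with_charge=with_charge)
        for frag, n in counts.items():
            acc[frag] = acc.get(frag, 0) + sign * coef * n


def reaction_difference_fingerprint(
    reaction: "Reaction",
    compounds: Mapping[str, MoleculeGraph | None],
    max_len: int,
    *,
    directed: bool = False,
    with_charge: bool = False,
) -> ReactionDifferenceFingerprint:
    """Stoichiometry-weighted reactant-minus-product fragment counts.

    Every compound in the equation participates with its full structure;
    exact-zero entries are dropped.  Raises :class:`MissingStructureError`
    naming the first compound without a structure, and
    :class:`CoefficientError` on symbolic or non-positive coefficients.
    """
    acc: dict[str, int] = {}
    _weighted_side(reaction.reactants, compounds, max_len, directed, with_charge, +1, acc)
    _weighted_side(reaction.products, compounds, max_len, directed, with_charge, -1, acc)
    return ReactionDifferenceFingerprint(
        {k: v for k, v in acc.items() if v != 0}, max_len, directed)


def _check_comparable(a: ReactionDifferenceFingerprint,
                      b: ReactionDifferenceFingerprint) -> None:
    if a.max_len != b.max_len:
        raise DialectMismatchError(
            f"cannot compare fingerprints with max_len {a.max_len} and {b.max_len}")
    if a.directed != b.directed:
        raise DialectMismatchError(
            "cannot compare directed-counted with deduplicated fingerprints")


def squared_euclidean_distance(a: ReactionDifferenceFingerprint,
                               b: ReactionDifferenceFingerprint) -> int:
    """Exact integer squared distance over the key union."""
    _check_comparable(a, b)
    total = 0
    for k, va in a.entries.items():
        d = va - b.entries.get(k, 0)
        total += d * d
    for k, vb in b.entries.items():
        if k not in a.entries:
            total += vb * vb
    return total


def euclidean_distance(a: ReactionDifferenceFingerprint,
                       b: ReactionDifferenceFingerprint) -> float:
    """Euclidean reaction distance D(a, b); absent keys read as zero."""
    return math.sqrt(squared_euclidean_distance(a, b))


def write_rfp_tsv(path, rfp: ReactionDifferenceFingerprint, *,
                  with_charge: bool = False, reaction_id: str | None = None) -> None:
    """Serialize an RFP as ``fragment<TAB>signed count`` with a dialect header."""
    from . import __version__
    lines = [f"# rxndiff {__version__} reaction difference fingerprint"]
    if reaction_id:
        lines.append(f"# reaction={reaction_id}")
    lines.append(
        f"# max_len={rfp.max_len} directed={rfp.directed} with_charge={with_charge}")
    lines.append("fragment\tdifference")
    for frag in sorted(rfp.entries):
        lines.append(f"{frag}\t{rfp.entries[frag]:+d}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
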