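"""Shared fixtures: worked-example structures and seeded synthetic sets."""
from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import settings

import rxndiff
from rxndiff import worked_examples as wx

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_compounds():
    """Parsed structures for the literature worked-example reactions."""
    return wx.compound_graphs()


@pytest.fixture(scope="session")
def synthetic_set():
    """Default-condition synthetic corpus (6 templates x 5 reactions)."""
    return rxndiff.generate_reaction_set(seed=0)


@pytest.fixture(scope="session")
def synthetic_graphs(synthetic_set):
    return synthetic_set.compound_graphs()


def brute_force_fragments(mol, max_len, directed=False):
    """Independent simple-path enumeration via networkx.

    Counts every single atom, then for every unordered atom pair every
    simple path of <= max_len edges, canonicalised as the lexicographic
    minimum of the two spellings.
    """
    import networkx as nx

    g = nx.Graph()
    symbols = [a.symbol() for a in mol.atoms]
    for i in range(mol.num_atoms):
        g.add_node(i)
    order = {}
    for i, j, o in mol.bonds:
        g.add_edge(i, j)
        order[frozenset((i, j))] = o
    counts: Counter = Counter()
    for s in symbols:
        counts[s] += 1
    if max_len >= 1:
        for i in range(mol.num_atoms):
            for j in range(i + 1, mol.num_atoms):
                for path in nx.all_simple_paths(g, i, j, cutoff=max_len):
                    tokens = [symbols[path[0]]]
                    for a, b in zip(path, path[1:]):
                        tokens.append(order[frozenset((a, b))])
                        tokens.append(symbols[b])
                    forward = "".join(tokens)
                    backward = "".join(reversed(tokens))
                    counts[min(forward, backward)] += 2 if directed else 1
    return dict(counts)


def random_molecule_graph(rng, max_atoms=10):
    """A random connected-ish heavy-atom graph (no aromaticity)."""
    from rxndiff.chemgraph import Atom, MoleculeGraph

    n = rng.randint(1, max_atoms)
    atoms = tuple(Atom(rng.choice("CNOSP")) for _ in range(n))
    bonds = []
    seen = set()
    # random spanning edges keep most graphs connected; extra edges add rings
    for j in range(1, n):
        i = rng.randrange(j)
        seen.add((i, j))
        bonds.append((i, j, rng.choice("-=#")))
    for _ in range(rng.randint(0, n)):
        i, j = rng.randrange(n), rng.randrange(n)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        bonds.append((key[0], key[1], rng.choice("-=#")))
    return MoleculeGraph(atoms=atoms, bonds=tuple(bonds))
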