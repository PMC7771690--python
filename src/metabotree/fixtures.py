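"""Deterministic synthetic inputs: worked-example toy tables and clade fixtures.

Two families of fixtures:

* exact reproductions of the worked two-organism example (an 11-reaction
  presence matrix with its per-reaction alignment-score row, and a 3 × 4
  enzyme score matrix for one shared reaction);

* clade-structured generators that emulate the strata observed in real
  organism sets — core reactions carried by everyone (high penetration),
  clade-specific reactions (medium penetration), and private per-organism
  reactions (low penetration) — plus clade-correlated protein sequences
  evolved down the clade tree by independent per-site substitution.

Everything is reproducible: the same CladeSpec (seed included) yields
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzyme_similarity import ABSENT_BOTH, ONE_SIDED, ReactionScoreTable
from .org_matrix import OrgMatrix, ReactionCatalog
from .treebuild import PhyloTree, TreeNode

__all__ = [
    "CladeSpec",
    "table5_fixture",
    "table6_fixture",
    "two_clade_spec",
    "generate_clade_matrix",
    "generate_clade_sequences",
    "planted_tree",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def table5_fixture() -> tuple[OrgMatrix, ReactionScoreTable]:
    """Two organisms, eleven reactions, with the per-reaction score row.

    Organism A carries 7 reactions and B 5; they share four (R01, R06, R07,
    R11) with alignment scores 0.87, 0.93, 0.75, 0.89; four reactions are
    one-sided and three are absent from both.
    """
    reactions = [f"R{i:02d}" for i in range(1, 12)]
    presence = np.array(
        [
            [1, 1, 0, 0, 1, 1, 1, 1, 0, 0, 1],  # A
            [1, 0, 0, 0, 0, 1, 1, 0, 0, 1, 1],  # B
        ],
        dtype=np.uint8,
    )
    m = OrgMatrix(["A", "B"], ReactionCatalog(reactions), presence)
    row: list[float | str] = [0.87, ONE_SIDED, ABSENT_BOTH, ABSENT_BOTH, ONE_SIDED,
                              0.93, 0.75, ONE_SIDED, ABSENT_BOTH, ONE_SIDED, 0.89]
    table = ReactionScoreTable("A", "B", dict(zip(reactions, row)))
    return m, table


def table6_fixture() -> np.ndarray:
    """3 × 4 normalized enzyme-pair score matrix for one shared reaction."""
    return np.array(
        [
            [0.87, 0.48, 0.81, 0.83],
            [0.65, 0.55, 0.23, 0.78],
            [0.78, 0.69, 0.55, 0.62],
        ]
    )


NestedClade = tuple  # nested tuples of organism IDs (strings at the leaves)


@dataclass(frozen=True)
class CladeSpec:
    """Recipe for a clade-structured ORG matrix with optional sequences.

    ``clade_tree`` is a nested tuple of organism IDs; every internal grouping
    below the root receives ``n_clade`` reactions shared by exactly its
    members.  ``n_core`` reactions are shared by all organisms and each
    organism carries ``n_private`` reactions of its own.  Sequences start
    from a random root sequence per reaction and accumulate independent
    per-site substitutions with probability ``substitution_prob`` on every
    edge of the clade tree.
    """

    clade_tree: NestedClade
    n_core: int = 40
    n_clade: int = 10
    n_private: int = 3
    seq_length: int = 120
    substitution_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_core, self.n_clade, self.n_private) < 0:
            raise ValueError("reaction counts must be non-negative")
        if not (0 <= self.substitution_prob < 1):
            raise ValueError("substitution probability must be in [0, 1)")
        orgs = self.organism_ids()
        if len(set(orgs)) != len(orgs):
            raise ValueError("overlapping organism IDs in clade tree")

    def organism_ids(self) -> list[str]:
        return _leaves(self.clade_tree)


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    out: list[str] = []
    for child in node:
        out.extend(_leaves(child))
    return out


def _internal_groups(node, path=()) -> list[tuple[str, list[str]]]:
    """(group_id, member list) for every internal grouping below the root."""
    groups: list[tuple[str, list[str]]] = []
    if isinstance(node, str):
        return groups
    if path:  # root handled by the core stratum
        groups.append(("-".join(map(str, path)), _leaves(node)))
    for i, child in enumerate(node):
        groups.extend(_internal_groups(child, path + (i,)))
    return groups


def two_clade_spec(
    n_per_clade: int = 10,
    n_core: int = 40,
    n_clade: int = 10,
    n_private: int = 3,
    seq_length: int = 120,
    substitution_prob: float = 0.05,
    seed: int = 0,
) -> CladeSpec:
    """Two balanced binary clades A1.. / B1.. of equal size.

    Each clade is split recursively into halves, so sister groups are always
    of (near-)equal size and the cluster-average distances of UPGMA recover
    the planted topology exactly.
    """

    def balanced(ids: list[str]) -> NestedClade | str:
        if len(ids) == 1:
            return ids[0]
        half = len(ids) // 2
        return (balanced(ids[:half]), balanced(ids[half:]))

    def clade(prefix: str) -> NestedClade:
        return balanced([f"{prefix}{i}" for i in range(1, n_per_clade + 1)])  # type: ignore[return-value]

    return CladeSpec(
        clade_tree=(clade("A"), clade("B")),
        n_core=n_core,
        n_clade=n_clade,
        n_private=n_private,
        seq_length=seq_length,
        substitution_prob=substitution_prob,
        seed=seed,
    )


def generate_clade_matrix(spec: CladeSpec) -> OrgMatrix:
    """Build the presence matrix planted by a CladeSpec.

    Reaction IDs encode their stratum: ``CORE####`` (all organisms),
    ``CLD<group>-####`` (one internal grouping), ``PRV-<org>-####`` (one
    organism).  Deterministic given the spec.
    """
    organisms = spec.organism_ids()
    groups = _internal_groups(spec.clade_tree)
    reactions: list[str] = [f"CORE{i:04d}" for i in range(spec.n_core)]
    membership: list[list[str]] = [organisms] * spec.n_core
    for gid, members in groups:
        if len(members) < 2:
            continue  # single-organism groupings are covered by private reactions
        for i in range(spec.n_clade):
            reactions.append(f"CLD{gid}-{i:04d}")
            membership.append(members)
    for org in organisms:
        for i in range(spec.n_private):
            reactions.append(f"PRV-{org}-{i:04d}")
            membership.append([org])
    presence = np.zeros((len(organisms), len(reactions)), dtype=np.uint8)
    oidx = {o: i for i, o in enumerate(organisms)}
    for j, members in enumerate(membership):
        for org in members:
            presence[oidx[org], j] = 1
    return OrgMatrix(organisms, ReactionCatalog(reactions), presence)


def generate_clade_sequences(m: OrgMatrix, spec: CladeSpec) -> OrgMatrix:
    """Attach clade-correlated protein sequences to every present cell.

    One random root sequence per reaction; each edge of the clade tree
    applies independent per-site substitutions (uniform over the 19
    alternative residues) with probability ``spec.substitution_prob``, so
    organisms in the same clade receive more similar sequences than
    cross-clade pairs.  Returns a new matrix sharing the presence table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    sequences: dict[tuple[str, str], list[str]] = {}
    ridx = {r: j for j, r in enumerate(m.catalog.reaction_ids)}
    oidx = {o: i for i, o in enumerate(m.organism_ids)}

    def mutate(seq: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hits = np.flatnonzero(rng.random(len(seq)) < spec.substitution_prob)
        if hits.size:
            # shift by 1..19 modulo 20: always a different residue
            out[hits] = (out[hits] + rng.integers(1, 20, size=hits.size)) % 20
        return out

    def descend(node, seq: np.ndarray, rxn: str) -> None:
        if isinstance(node, str):
            if m.presence[oidx[node], ridx[rxn]]:
                sequences[(node, rxn)] = ["".join(AA20[k] for k in seq)]
            return
        for child in node:
            descend(child, mutate(seq), rxn)

    for rxn in m.catalog.reaction_ids:
        root_seq = rng.integers(0, 20, size=spec.seq_length)
        descend(spec.clade_tree, root_seq, rxn)
    return OrgMatrix(list(m.organism_ids), m.catalog, m.presence, sequences)


def planted_tree(spec: CladeSpec) -> PhyloTree:
    """The clade tree of a spec as a PhyloTree (topology only, unit branches)."""

    def build(node) -> TreeNode:
        if isinstance(node, str):
            return TreeNode(label=node, branch_length=1.0)
        return TreeNode(children=[build(c) for c in node], branch_length=1.0)

    root = build(spec.clade_tree)
    root.branch_length = None
    return PhyloTree(root)
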