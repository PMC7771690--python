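"""Enzyme-sequence organism similarity over a (possibly restricted) reaction set.

For every reaction shared by two organisms, all enzyme sequences of the one
are locally aligned against all enzyme sequences of the other
(Smith–Waterman, BLOSUM50, linear gap cost 8 by default).  Each raw score is
normalized by the first sequence's self-alignment score,

    S_R(A_i, B_j) = sw(A_i, B_j) / sw(A_i, A_i),

so scores are relative to the query and the directed comparison is not
symmetric.  The reaction-level score takes the maximum over all enzyme pairs
(isozymes / complex subunits), and the organism-level score averages the
reaction-level scores, with reactions present in exactly one organism either
skipped ("ignore") or contributing a scalar penalty value.  Reactions absent
from both organisms never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .org_matrix import ConsistencyError, OrgMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "AlignmentConfig",
    "PenaltyPolicy",
    "ReactionScoreTable",
    "ONE_SIDED",
    "ABSENT_BOTH",
    "normalized_sw",
    "reaction_score",
    "average_reaction_scores",
    "organism_similarity",
    "pairwise_sequence_similarity",
    "read_reaction_subset",
]

#: Status markers for reactions that yield no alignment score for a pair.
ONE_SIDED = "ONE_SIDED"
ABSENT_BOTH = "ABSENT_BOTH"


@dataclass(frozen=True)
class AlignmentConfig:
    """Local-alignment scoring parameters.

    ``gap_open``/``gap_extend`` are positive costs; equal values give the
    linear gap model.  The matrix name must resolve through
    :mod:`Bio.Align.substitution_matrices`.
    """

    matrix: str = "BLOSUM50"
    gap_open: float = 8.0
    gap_extend: float = 8.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        _load_matrix(self.matrix)  # fail early on unknown name


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(cfg: AlignmentConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(cfg.matrix)
    aligner.open_gap_score = -cfg.gap_open
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


@dataclass(frozen=True)
class PenaltyPolicy:
    """How one-sided reactions (present in exactly one organism) are scored.

    ``mode="value"`` contributes the scalar ``value`` to the average;
    ``mode="ignore"`` drops the reaction from the comparison entirely.
    """

    mode: str = "value"
    value: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("value", "ignore"):
            raise ValueError(f"penalty mode must be 'value' or 'ignore', got {self.mode!r}")

    @classmethod
    def ignore(cls) -> "PenaltyPolicy":
        return cls(mode="ignore", value=0.0)

    @classmethod
    def parse(cls, text: str) -> "PenaltyPolicy":
        """Parse a CLI-style penalty: a real number, or the literal 'ignore'."""
        if text.strip().lower() == "ignore":
            return cls.ignore()
        return cls(mode="value", value=float(text))


def raw_sw_score(seq_a: str, seq_b: str, cfg: AlignmentConfig | None = None) -> float:
    """Raw Smith–Waterman local alignment score."""
    cfg = cfg or AlignmentConfig()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    return float(_aligner(cfg).score(seq_a.upper(), seq_b.upper()))


def normalized_sw(seq_a: str, seq_b: str, cfg: AlignmentConfig | None = None) -> float:
    """Local alignment score of ``seq_a`` vs ``seq_b``, normalized by seq_a's self-score.

    The normalization is by the first argument's self-alignment, so
    ``normalized_sw(a, b)`` and ``normalized_sw(b, a)`` generally differ.
    """
    cfg = cfg or AlignmentConfig()
    self_score = raw_sw_score(seq_a, seq_a, cfg)
    assert self_score > 0, "self-alignment score must be positive for standard matrices"
    return raw_sw_score(seq_a, seq_b, cfg) / self_score


def reaction_score(
    seqs_a: list[str], seqs_b: list[str], cfg: AlignmentConfig | None = None
) -> float:
    """Reaction-level score: maximum normalized score over all enzyme pairs.

    With isozymes or complex subunits on either side, the best-matching pair
    defines the score, independent of how many sequences are present.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("both sequence lists must be non-empty")
    return max(normalized_sw(a, b, cfg) for a in seqs_a for b in seqs_b)


def score_matrix_max(matrix: np.ndarray) -> float:
    """Aggregate an all-against-all enzyme score matrix to a reaction score."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty score matrix")
    return float(matrix.max())


@dataclass
class ReactionScoreTable:
    """Per-reaction outcome of a directed organism pair comparison.

    ``entries`` maps reaction → score (shared), ONE_SIDED, or ABSENT_BOTH.
    """

    org_a: str
    org_b: str
    entries: dict[str, float | str] = field(default_factory=dict)

    def shared_scores(self) -> list[float]:
        return [v for v in self.entries.values() if not isinstance(v, str)]

    def one_sided_count(self) -> int:
        return sum(1 for v in self.entries.values() if v == ONE_SIDED)

    def n_contributing(self, penalty: PenaltyPolicy) -> int:
        n = len(self.shared_scores())
        if penalty.mode == "value":
            n += self.one_sided_count()
        return n

    def to_rows(self) -> list[tuple[str, str, str, str, str]]:
        """Long-format rows (org_a, org_b, reaction, status, score) for TSV export."""
        rows = []
        for rxn, v in self.entries.items():
            if isinstance(v, str):
                rows.append((self.org_a, self.org_b, rxn, v, ""))
            else:
                rows.append((self.org_a, self.org_b, rxn, "SHARED", repr(v)))
        return rows


def average_reaction_scores(table: ReactionScoreTable, penalty: PenaltyPolicy) -> float:
    """⟨S(A,B)⟩: mean of contributing per-reaction entries.

    Shared reactions contribute their alignment score; one-sided reactions
    contribute the penalty value (or nothing in ignore mode); reactions absent
    from both organisms are always excluded from the mean.
    """
    shared = table.shared_scores()
    n_one = table.one_sided_count()
    if penalty.mode == "value":
        total = sum(shared) + penalty.value * n_one
        n_r = len(shared) + n_one
    else:
        total = sum(shared)
        n_r = len(shared)
    if n_r == 0:
        raise ValueError(
            f"no contributing reactions between {table.org_a!r} and {table.org_b!r}; "
            "similarity undefined"
        )
    return total / n_r


def organism_similarity(
    m: OrgMatrix,
    org_a: str,
    org_b: str,
    reaction_subset: list[str] | None = None,
    penalty: PenaltyPolicy | None = None,
    cfg: AlignmentConfig | None = None,
) -> tuple[float, ReactionScoreTable]:
    """Directed sequence similarity ⟨S(A,B)⟩ between two organisms.

    The comparison can be restricted to a reaction subset (which must be a
    subset of the catalog).  Returns the score and the per-reaction table.
    """
    penalty = penalty or PenaltyPolicy()
    cfg = cfg or AlignmentConfig()
    ia, ib = m.organism_index(org_a), m.organism_index(org_b)
    scope = _subset_scope(m, reaction_subset)
    table = ReactionScoreTable(org_a, org_b)
    ridx = {r: j for j, r in enumerate(m.catalog.reaction_ids)}
    for rxn in scope:
        j = ridx[rxn]
        in_a, in_b = bool(m.presence[ia, j]), bool(m.presence[ib, j])
        if in_a and in_b:
            table.entries[rxn] = reaction_score(
                m.sequences_for(org_a, rxn), m.sequences_for(org_b, rxn), cfg
            )
        elif in_a or in_b:
            table.entries[rxn] = ONE_SIDED
        else:
            table.entries[rxn] = ABSENT_BOTH
    return average_reaction_scores(table, penalty), table


def _subset_scope(m: OrgMatrix, reaction_subset: list[str] | None) -> list[str]:
    if reaction_subset is None:
        return list(m.catalog.reaction_ids)
    known = set(m.catalog.reaction_ids)
    stray = [r for r in reaction_subset if r not in known]
    if stray:
        raise ConsistencyError(f"reaction subset contains unknown reactions: {stray}")
    return list(reaction_subset)


def pairwise_sequence_similarity(
    m: OrgMatrix,
    reaction_subset: list[str] | None = None,
    penalty: PenaltyPolicy | None = None,
    cfg: AlignmentConfig | None = None,
) -> SimilarityMatrix:
    """All-to-all sequence similarity matrix, symmetrized by averaging directions.

    Because the per-enzyme normalization is by the query's self-score, the
    directed scores ⟨S(A,B)⟩ and ⟨S(B,A)⟩ differ in general; the matrix entry
    is their mean (recorded in the parameters), which downstream clustering
    requires to be symmetric.
    """
    penalty = penalty or PenaltyPolicy()
    cfg = cfg or AlignmentConfig()
    n = m.n_organisms
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            s_ab, _ = organism_similarity(
                m, m.organism_ids[i], m.organism_ids[j], reaction_subset, penalty, cfg
            )
            s_ba, _ = organism_similarity(
                m, m.organism_ids[j], m.organism_ids[i], reaction_subset, penalty, cfg
            )
            values[i, j] = values[j, i] = 0.5 * (s_ab + s_ba)
    params = {
        "penalty_mode": penalty.mode,
        "penalty_value": penalty.value if penalty.mode == "value" else None,
        "matrix": cfg.matrix,
        "gap_open": cfg.gap_open,
        "gap_extend": cfg.gap_extend,
        "reaction_subset_size": None if reaction_subset is None else len(reaction_subset),
        "symmetrization": "mean_of_directed",
    }
    return SimilarityMatrix(list(m.organism_ids), values, "sequence", params)


def read_reaction_subset(path: str | Path) -> list[str]:
    """Read a reaction-subset file: one reaction ID per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
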