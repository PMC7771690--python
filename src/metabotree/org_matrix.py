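"""Organism–reaction(–sequence) matrix: data model, I/O and penetration statistics.

The central object is the ORG matrix: a binary organisms × reactions presence
table, optionally annotated with the amino-acid sequences of the enzymes that
implement each present reaction, and with reaction → compound and
reaction → pathway annotation tables.

Penetration of a reaction is the fraction of organisms carrying it.  Reactions
are classed as low penetration (LP, fraction < 10%), medium (MP, 35–65%) or
high (HP, > 90%); fractions in the two gaps are left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReactionCatalog",
    "OrgMatrix",
    "PenetrationProfile",
    "PenetrationNull",
    "OrgMatrixFormatError",
    "ConsistencyError",
    "AnnotationError",
    "read_org_matrix",
    "write_org_matrix",
    "read_annotation_table",
    "penetration_profile",
    "organism_composition",
    "random_penetration_null",
    "lp_hp_overlap",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

LP = "LP"
MP = "MP"
HP = "HP"
UNCLASSIFIED = "UNCLASSIFIED"


class OrgMatrixFormatError(ValueError):
    """Malformed presence matrix (duplicate IDs, non-binary entries...)."""


class ConsistencyError(ValueError):
    """Inputs that disagree with each other (e.g. a sequence for an absent reaction)."""


class AnnotationError(ValueError):
    """Missing compound/pathway annotation for a classified reaction."""


@dataclass
class ReactionCatalog:
    """The universe of reactions, with optional compound and pathway annotation.

    ``compounds``/``pathways`` map a reaction ID to a (possibly empty) set of
    compound / pathway IDs; an empty pathway set means "no pathway assigned".
    """

    reaction_ids: list[str]
    compounds: dict[str, set[str]] | None = None
    pathways: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.reaction_ids) < 1:
            raise OrgMatrixFormatError("catalog must contain at least one reaction")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise OrgMatrixFormatError("duplicate reaction IDs in catalog")
        known = set(self.reaction_ids)
        for name, table in (("compounds", self.compounds), ("pathways", self.pathways)):
            if table is not None:
                stray = set(table) - known
                if stray:
                    raise OrgMatrixFormatError(
                        f"{name} annotation refers to unknown reactions: {sorted(stray)}"
                    )

    @property
    def total_count(self) -> int:
        """R_T: number of reactions in the catalog."""
        return len(self.reaction_ids)


@dataclass
class OrgMatrix:
    """Binary organisms × reactions presence table with optional sequences.

    ``presence`` is an N × R_T uint8 array aligned with ``organism_ids`` (rows)
    and ``catalog.reaction_ids`` (columns).  ``sequences`` maps
    (organism_id, reaction_id) → non-empty list of amino-acid sequences and is
    defined only for cells with presence 1.
    """

    organism_ids: list[str]
    catalog: ReactionCatalog
    presence: np.ndarray
    sequences: dict[tuple[str, str], list[str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.organism_ids)) != len(self.organism_ids):
            raise OrgMatrixFormatError("duplicate organism IDs")
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.organism_ids), self.catalog.total_count):
            raise OrgMatrixFormatError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.organism_ids)} organisms x {self.catalog.total_count} reactions"
            )
        if not np.isin(self.presence, (0, 1)).all():
            raise OrgMatrixFormatError("presence entries must be 0 or 1")
        if (self.presence.sum(axis=1) == 0).any():
            empty = [o for o, s in zip(self.organism_ids, self.presence.sum(axis=1)) if s == 0]
            raise OrgMatrixFormatError(f"organisms with no present reaction: {empty}")
        if self.sequences:
            self._validate_sequences()

    def _validate_sequences(self) -> None:
        oidx = {o: i for i, o in enumerate(self.organism_ids)}
        ridx = {r: j for j, r in enumerate(self.catalog.reaction_ids)}
        for (org, rxn), seqs in self.sequences.items():
            if org not in oidx or rxn not in ridx:
                raise ConsistencyError(f"sequence for unknown cell ({org}, {rxn})")
            if self.presence[oidx[org], ridx[rxn]] != 1:
                raise ConsistencyError(
                    f"sequence attached to absent reaction: organism {org}, reaction {rxn}"
                )
            if not seqs:
                raise ConsistencyError(f"empty sequence list for ({org}, {rxn})")
            for s in seqs:
                bad = set(s.upper()) - AA_ALPHABET
                if not s or bad:
                    raise ConsistencyError(
                        f"invalid amino-acid sequence for ({org}, {rxn}): "
                        f"{'empty' if not s else 'letters ' + ''.join(sorted(bad))}"
                    )

    @property
    def n_organisms(self) -> int:
        return len(self.organism_ids)

    def organism_index(self, organism_id: str) -> int:
        try:
            return self.organism_ids.index(organism_id)
        except ValueError:
            raise KeyError(f"unknown organism {organism_id!r}") from None

    def reaction_counts(self) -> np.ndarray:
        """Per-organism number of present reactions (R_i)."""
        return self.presence.sum(axis=1).astype(int)

    def present_reactions(self, organism_id: str) -> list[str]:
        row = self.presence[self.organism_index(organism_id)]
        return [r for r, v in zip(self.catalog.reaction_ids, row) if v]

    def orphan_reactions(self) -> list[str]:
        """Reactions retained in the catalog but absent from every organism."""
        col = self.presence.sum(axis=0)
        return [r for r, v in zip(self.catalog.reaction_ids, col) if v == 0]

    def sequences_for(self, organism_id: str, reaction_id: str) -> list[str]:
        if not self.sequences:
            raise ConsistencyError("matrix carries no sequences")
        try:
            return self.sequences[(organism_id, reaction_id)]
        except KeyError:
            raise ConsistencyError(
                f"no sequence recorded for present cell ({organism_id}, {reaction_id})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence,
            index=pd.Index(self.organism_ids, name="organism"),
            columns=self.catalog.reaction_ids,
        )


def read_org_matrix(matrix_path: str | Path, fasta_path: str | Path | None = None) -> OrgMatrix:
    """Read a tab-separated presence matrix and optional enzyme FASTA.

    The matrix file has a header row of reaction IDs, a first column of
    organism IDs and entries in {0, 1}.  FASTA headers follow the dialect
    ``orgID|reactionID[|geneID]``; every record must point at a presence-1
    cell.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise OrgMatrixFormatError(f"duplicate organism IDs: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise OrgMatrixFormatError(f"duplicate reaction IDs: {dups}")
    values = np.zeros(df.shape, dtype=np.uint8)
    for i, org in enumerate(df.index):
        for j, rxn in enumerate(df.columns):
            cell = df.iat[i, j]
            if cell not in ("0", "1"):
                raise OrgMatrixFormatError(
                    f"non-binary entry {cell!r} at organism {org!r}, reaction {rxn!r}"
                )
            values[i, j] = int(cell)
    catalog = ReactionCatalog(list(df.columns))
    sequences: dict[tuple[str, str], list[str]] | None = None
    if fasta_path is not None:
        sequences = _read_sequence_fasta(fasta_path)
    m = OrgMatrix(list(df.index), catalog, values, sequences or None)
    return m


def _read_sequence_fasta(fasta_path: str | Path) -> dict[tuple[str, str], list[str]]:
    sequences: dict[tuple[str, str], list[str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise OrgMatrixFormatError(
                f"FASTA header {rec.id!r} does not follow 'org|reaction[|gene]'"
            )
        org, rxn = parts[0], parts[1]
        sequences.setdefault((org, rxn), []).append(str(rec.seq).upper())
    return sequences


def write_org_matrix(m: OrgMatrix, matrix_path: str | Path, fasta_path: str | Path | None = None) -> None:
    """Write the presence table (and sequences, if any) in the dialect read_org_matrix reads."""
    m.to_frame().to_csv(matrix_path, sep="\t")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for (org, rxn), seqs in sorted((m.sequences or {}).items()):
                for g, seq in enumerate(seqs, start=1):
                    fh.write(f">{org}|{rxn}|g{g}\n{seq}\n")


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read a long-format 'reaction<TAB>value' table into reaction → set of values.

    A row with an empty second field records the reaction with an empty set
    (used for 'no pathway assigned').
    """
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rxn = parts[0]
            value = parts[1] if len(parts) > 1 else ""
            table.setdefault(rxn, set())
            if value:
                table[rxn].add(value)
    return table


@dataclass
class PenetrationProfile:
    """Per-reaction organism counts, fractions and LP/MP/HP class labels.

    Reactions absent from every organism are excluded.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    classes: dict[str, str]
    n_organisms: int
    thresholds: dict[str, float] = field(default_factory=dict)

    def reactions_in_class(self, cls: str) -> list[str]:
        return [r for r, c in self.classes.items() if c == cls]


def classify_fraction(f: float, lp_max: float, mp_lo: float, mp_hi: float, hp_min: float) -> str:
    if f < lp_max:
        return LP
    if f > hp_min:
        return HP
    if mp_lo <= f <= mp_hi:
        return MP
    return UNCLASSIFIED


def penetration_profile(
    m: OrgMatrix,
    lp_max: float = 0.10,
    mp_lo: float = 0.35,
    mp_hi: float = 0.65,
    hp_min: float = 0.90,
) -> PenetrationProfile:
    """Classify every reaction present in ≥1 organism by penetration fraction.

    LP iff fraction < ``lp_max``; HP iff fraction > ``hp_min``; MP iff
    ``mp_lo`` ≤ fraction ≤ ``mp_hi``; the two gaps are UNCLASSIFIED.
    """
    if not (0 < lp_max <= mp_lo <= mp_hi <= hp_min < 1):
        raise ValueError(
            f"thresholds must satisfy 0 < lp_max <= mp_lo <= mp_hi <= hp_min < 1, "
            f"got {lp_max}, {mp_lo}, {mp_hi}, {hp_min}"
        )
    n = m.n_organisms
    col_counts = m.presence.sum(axis=0).astype(int)
    counts: dict[str, int] = {}
    fractions: dict[str, float] = {}
    classes: dict[str, str] = {}
    for rxn, c in zip(m.catalog.reaction_ids, col_counts):
        if c == 0:
            continue
        f = c / n
        counts[rxn] = int(c)
        fractions[rxn] = f
        classes[rxn] = classify_fraction(f, lp_max, mp_lo, mp_hi, hp_min)
    return PenetrationProfile(
        counts,
        fractions,
        classes,
        n,
        {"lp_max": lp_max, "mp_lo": mp_lo, "mp_hi": mp_hi, "hp_min": hp_min},
    )


def organism_composition(m: OrgMatrix, p: PenetrationProfile) -> pd.DataFrame:
    """Per-organism fraction of its present reactions in each penetration class.

    Returns a DataFrame indexed by organism with columns LP, MP, HP and
    UNCLASSIFIED; rows sum to 1.
    """
    if p.n_organisms != m.n_organisms or set(p.counts) - set(m.catalog.reaction_ids):
        raise ConsistencyError("penetration profile does not match this matrix")
    rows = []
    for i, org in enumerate(m.organism_ids):
        present = [r for r, v in zip(m.catalog.reaction_ids, m.presence[i]) if v]
        tally = {LP: 0, MP: 0, HP: 0, UNCLASSIFIED: 0}
        for r in present:
            try:
                tally[p.classes[r]] += 1
            except KeyError:
                raise ConsistencyError(
                    f"reaction {r!r} present in {org!r} missing from profile"
                ) from None
        total = len(present)
        rows.append({cls: tally[cls] / total for cls in (LP, MP, HP, UNCLASSIFIED)})
    return pd.DataFrame(rows, index=pd.Index(m.organism_ids, name="organism"))


@dataclass
class PenetrationNull:
    """Random-reaction-set null model summary.

    ``histogram_mean``/``histogram_sd``: over replicates, mean and SD of the
    shared-reaction histogram h[k] = number of catalog reactions drawn by
    exactly k organisms (k = 0..N).  ``per_reaction_mean``: mean organism count
    per catalog reaction across replicates.
    """

    histogram_mean: np.ndarray
    histogram_sd: np.ndarray
    per_reaction_mean: np.ndarray
    replicates: int
    seed: int

    @property
    def expected_count(self) -> float:
        """Analytic per-reaction expectation Σ_i R_i / R_T (uniform draws)."""
        return float(self.per_reaction_mean.mean())


def random_penetration_null(m: OrgMatrix, replicates: int, seed: int) -> PenetrationNull:
    """Null penetration model: each organism draws its true reaction count uniformly.

    Per replicate, organism i receives R_i reactions sampled uniformly without
    replacement from the whole catalog; the per-count histogram and per-reaction
    counts are accumulated over replicates.  Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n, r_t = m.n_organisms, m.catalog.total_count
    r_i = m.reaction_counts()
    hist = np.zeros((replicates, n + 1), dtype=np.int64)
    count_sum = np.zeros(r_t, dtype=np.float64)
    for rep in range(replicates):
        # random ranking per row: first R_i columns of argsort = uniform subset
        order = rng.random((n, r_t)).argsort(axis=1)
        counts = np.zeros(r_t, dtype=np.int64)
        for i in range(n):
            counts[order[i, : r_i[i]]] += 1
        hist[rep] = np.bincount(counts, minlength=n + 1)
        count_sum += counts
    return PenetrationNull(
        histogram_mean=hist.mean(axis=0),
        histogram_sd=hist.std(axis=0),
        per_reaction_mean=count_sum / replicates,
        replicates=replicates,
        seed=seed,
    )


def lp_hp_overlap(catalog: ReactionCatalog, p: PenetrationProfile) -> dict[str, float]:
    """Overlap statistics between the LP and HP reaction sets.

    Returns fractions of: LP reactions sharing no compound with any HP
    reaction; LP reactions with an empty pathway set; HP reactions with an
    empty pathway set.  NaN (with a warning) where the class is empty.
    """
    lp = p.reactions_in_class(LP)
    hp = p.reactions_in_class(HP)
    if catalog.compounds is None or catalog.pathways is None:
        raise AnnotationError("catalog lacks compound and/or pathway annotation")
    missing = [r for r in lp + hp if r not in catalog.compounds or r not in catalog.pathways]
    if missing:
        raise AnnotationError(f"classified reactions without annotation: {sorted(set(missing))}")
    out: dict[str, float] = {}
    hp_compounds: set[str] = set()
    for r in hp:
        hp_compounds |= catalog.compounds[r]
    if lp:
        no_shared = sum(1 for r in lp if not (catalog.compounds[r] & hp_compounds))
        out["lp_no_shared_compound"] = no_shared / len(lp)
        out["lp_no_pathway"] = sum(1 for r in lp if not catalog.pathways[r]) / len(lp)
    else:
        warnings.warn("LP class is empty; LP overlap fractions undefined", stacklevel=2)
        out["lp_no_shared_compound"] = float("nan")
        out["lp_no_pathway"] = float("nan")
    if hp:
        out["hp_no_pathway"] = sum(1 for r in hp if not catalog.pathways[r]) / len(hp)
    else:
        warnings.warn("HP class is empty; HP pathway fraction undefined", stacklevel=2)
        out["hp_no_pathway"] = float("nan")
    return out
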