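"""Binary metabolic-network fingerprint comparison via the Jaccard index.

Two organisms' metabolic repertoires are compared as sets of reactions:
J(A, B) = |A ∩ B| / |A ∪ B|.  Reactions absent from both organisms carry no
information and never enter the score.
"""

from __future__ import annotations

import numpy as np

from .org_matrix import OrgMatrix
from .similarity import SimilarityMatrix

__all__ = ["jaccard", "pairwise_jaccard"]


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two equal-length binary presence vectors.

    Raises if both vectors are all-zero: an organism with no reactions carries
    no information to compare.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"presence vectors differ in length: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("both presence vectors are all-zero; Jaccard undefined")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def pairwise_jaccard(m: OrgMatrix) -> SimilarityMatrix:
    """All-to-all Jaccard similarity between the organisms of an ORG matrix.

    Columns empty across all loaded organisms are dropped before comparison
    (they cannot change any pairwise score).
    """
    if m.n_organisms < 2:
        raise ValueError("need at least 2 organisms")
    x = m.presence.astype(np.int64)
    x = x[:, x.sum(axis=0) > 0]
    row = x.sum(axis=1)
    if (row == 0).any():
        empty = [o for o, s in zip(m.organism_ids, row) if s == 0]
        raise ValueError(f"organisms with all-zero fingerprints: {empty}")
    inter = x @ x.T
    union = row[:, None] + row[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(m.organism_ids), values, "jaccard", {})
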