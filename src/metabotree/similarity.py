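"""Symmetric pairwise organism similarity matrices with method metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix"]


@dataclass
class SimilarityMatrix:
    """N × N symmetric organism similarity scores.

    ``method`` is ``"jaccard"`` or ``"sequence"``; ``parameters`` records the
    method-specific settings (penalty policy, alignment configuration,
    reaction-subset identifier) so a matrix is self-describing.
    """

    organism_ids: list[str]
    values: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.organism_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match {n} organisms")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.organism_ids.index(a), self.organism_ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.organism_ids, name="organism")
        return pd.DataFrame(self.values, index=idx, columns=self.organism_ids)

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the square TSV; optionally a JSON sidecar of method parameters."""
        self.to_frame().to_csv(path, sep="\t")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"method": self.method, "parameters": self.parameters}, fh, indent=2)
                fh.write("\n")

    @classmethod
    def read(cls, path: str | Path, sidecar: str | Path | None = None) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = {"method": "unknown", "parameters": {}}
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(list(df.index), df.to_numpy(), meta["method"], meta.get("parameters", {}))
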