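"""Relatedness matrices.

A :class:`KinshipMatrix` stores pairwise relatedness on the ``2Φ`` scale
(Φ = kinship coefficient): a non-inbred individual has a diagonal entry of
1 and a parent–offspring or full-sib pair an off-diagonal entry of 0.5.
Matrices derived from a genealogy (``source="pedigree"``) and matrices
estimated from genome-wide markers (``source="empirical"``) share this
container so either can be passed to the variance-component and
association models interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["KinshipMatrix", "read_kinship"]

_SYM_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Square symmetric relatedness matrix with named samples.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers; must be unique.
    values
        Square matrix aligned to ``sample_ids``; symmetrised on input.
    source
        ``"pedigree"`` or ``"empirical"``.
    postprocessed
        True once negative entries have been zeroed and the diagonal
        rescaled to exactly 1.
    n_negatives_zeroed
        Bookkeeping from postprocessing (None if never postprocessed).
    """

    sample_ids: list[str]
    values: np.ndarray
    source: str = "pedigree"
    postprocessed: bool = False
    n_negatives_zeroed: int | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"kinship matrix must be square, got shape {v.shape}")
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("sample_ids length does not match matrix dimension")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in kinship matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("kinship matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > _SYM_TOL * max(1.0, np.max(np.abs(v))):
            raise ValueError("kinship matrix is not symmetric")
        self.values = (v + v.T) / 2.0

    # -- indexing -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"sample {e.args[0]!r} not present in kinship matrix") from None

    def subset(self, ids) -> "KinshipMatrix":
        """Restrict to ``ids`` in the given order."""
        idx = self.index_of(ids)
        return replace(self, sample_ids=[str(s) for s in ids],
                       values=self.values[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    # -- I/O ----------------------------------------------------------

    def to_square_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.to_csv(path, index_label="id")

    def to_long_csv(self, path) -> None:
        ii, jj = np.tril_indices(self.n)
        pd.DataFrame({
            "id1": [self.sample_ids[i] for i in ii],
            "id2": [self.sample_ids[j] for j in jj],
            "value": self.values[ii, jj],
        }).to_csv(path, index=False)

    @classmethod
    def from_square_csv(cls, path, source: str = "empirical") -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("square kinship CSV must have matching row/column ids")
        return cls(sample_ids=list(df.index), values=df.to_numpy(float), source=source)

    @classmethod
    def from_long_csv(cls, path, source: str = "empirical") -> "KinshipMatrix":
        df = pd.read_csv(path, dtype={"id1": str, "id2": str})
        ids: list[str] = []
        seen = set()
        for s in pd.concat([df["id1"], df["id2"]]):
            if s not in seen:
                seen.add(s)
                ids.append(s)
        lookup = {s: i for i, s in enumerate(ids)}
        v = np.zeros((len(ids), len(ids)))
        for a, b, val in zip(df["id1"], df["id2"], df["value"]):
            v[lookup[a], lookup[b]] = val
            v[lookup[b], lookup[a]] = val
        return cls(sample_ids=ids, values=v, source=source)


def read_kinship(path, source: str = "empirical") -> KinshipMatrix:
    """Read a kinship matrix CSV, auto-detecting square vs long layout."""
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if [c.lower() for c in header[:3]] == ["id1", "id2", "value"]:
        return KinshipMatrix.from_long_csv(path, source=source)
    return KinshipMatrix.from_square_csv(path, source=source)
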