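"""Pedigree parsing, validation, and expected (genealogical) kinship.

The kinship coefficient Φ(i, j) is the probability that an allele drawn
at random from i and one drawn from j at the same autosomal locus are
identical by descent. It satisfies the classic recursion, evaluated with
parents before children:

    Φ(i, i) = ½ [1 + Φ(father(i), mother(i))]
    Φ(i, j) = ½ [Φ(father(i), j) + Φ(mother(i), j)]   (j not a descendant of i)

with founders mutually unrelated and non-inbred (Φ = ½ on the diagonal,
0 elsewhere). :func:`pedigree_kinship` returns the matrix on the 2Φ
scale, so a non-inbred diagonal is 1 + F with F the inbreeding
coefficient, directly comparable to a marker-based relationship matrix.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix

__all__ = [
    "Pedigree",
    "PedigreeError",
    "DuplicateIndividualError",
    "UnknownParentError",
    "HalfSpecifiedParentError",
    "CyclicPedigreeError",
    "ParentSexError",
    "read_pedigree",
    "write_pedigree",
    "pedigree_kinship",
]

MISSING_PARENT = {"", "0", "NA", "na", None}

MALE, FEMALE, UNKNOWN = "M", "F", "U"

_SEX_CODES = {
    "1": MALE, "2": FEMALE, "0": UNKNOWN,
    "m": MALE, "f": FEMALE, "u": UNKNOWN,
    "male": MALE, "female": FEMALE, "unknown": UNKNOWN,
}


class PedigreeError(ValueError):
    """Base class for genealogy validation failures."""


class DuplicateIndividualError(PedigreeError):
    """Individual id repeated within a family."""


class UnknownParentError(PedigreeError):
    """A named parent has no record in the same family."""


class HalfSpecifiedParentError(PedigreeError):
    """Exactly one parent named; parentage must be both-known or both-missing."""


class CyclicPedigreeError(PedigreeError):
    """An individual is its own ancestor."""


class ParentSexError(PedigreeError):
    """A father is not male, or a mother is not female."""


@dataclass
class Pedigree:
    """Validated set of genealogy records.

    ``table`` has one row per individual with columns ``family_id``,
    ``individual_id``, ``father_id``, ``mother_id`` (None when missing)
    and ``sex`` in {"M", "F", "U"}. Founders are rows with both parents
    missing. Construction validates the invariants and precomputes a
    parent-before-child evaluation order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        for col in ("family_id", "individual_id", "father_id", "mother_id", "sex"):
            if col not in t.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
        for col in ("family_id", "individual_id"):
            t[col] = t[col].astype(str)
        for col in ("father_id", "mother_id"):
            t[col] = t[col].map(
                lambda v: None if (pd.isna(v) or str(v) in MISSING_PARENT) else str(v)
            )
        t["sex"] = t["sex"].map(lambda v: _SEX_CODES.get(str(v).lower(), str(v).upper()))
        if not set(t["sex"]).issubset({MALE, FEMALE, UNKNOWN}):
            bad = sorted(set(t["sex"]) - {MALE, FEMALE, UNKNOWN})
            raise PedigreeError(f"unrecognised sex codes: {bad}")
        self.table = t
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        t = self.table
        dup = t.duplicated(subset=["family_id", "individual_id"])
        if dup.any():
            fam, ind = t.loc[dup.idxmax(), ["family_id", "individual_id"]]
            raise DuplicateIndividualError(
                f"individual {ind!r} appears more than once in family {fam!r}")

        key = {(f, i): row for row, (f, i)
               in enumerate(zip(t["family_id"], t["individual_id"]))}
        n = len(t)
        father = np.full(n, -1, dtype=int)
        mother = np.full(n, -1, dtype=int)
        for row in range(n):
            fam = t.at[row, "family_id"]
            fa, mo = t.at[row, "father_id"], t.at[row, "mother_id"]
            if (fa is None) != (mo is None):
                raise HalfSpecifiedParentError(
                    f"individual {t.at[row, 'individual_id']!r} in family {fam!r} "
                    "names exactly one parent")
            if fa is None:
                continue
            for pid, arr, want in ((fa, father, MALE), (mo, mother, FEMALE)):
                if (fam, pid) not in key:
                    raise UnknownParentError(
                        f"parent {pid!r} of {t.at[row, 'individual_id']!r} "
                        f"not found in family {fam!r}")
                p = key[(fam, pid)]
                if t.at[p, "sex"] != want:
                    role = "father" if want == MALE else "mother"
                    raise ParentSexError(
                        f"{role} {pid!r} in family {fam!r} has sex "
                        f"{t.at[p, 'sex']!r}")
                arr[row] = p
        self._father, self._mother = father, mother

        # generations via Kahn; leftovers indicate a parentage cycle
        children: list[list[int]] = [[] for _ in range(n)]
        pending = np.zeros(n, dtype=int)
        for row in range(n):
            if father[row] >= 0:
                pending[row] = 2
                children[father[row]].append(row)
                children[mother[row]].append(row)
        gen = np.full(n, -1, dtype=int)
        heap = [row for row in range(n) if father[row] < 0]
        heapq.heapify(heap)
        for row in heap:
            gen[row] = 0
        order: list[int] = []
        while heap:
            row = heapq.heappop(heap)
            order.append(row)
            for c in children[row]:
                pending[c] -= 1
                gen[c] = max(gen[c], gen[row] + 1)
                if pending[c] == 0:
                    heapq.heappush(heap, c)
        if len(order) != n:
            stuck = t.loc[[r for r in range(n) if r not in set(order)],
                          "individual_id"].tolist()
            raise CyclicPedigreeError(
                f"cyclic parentage involving individuals {stuck}")
        self._generation = gen
        # parents before children; generation first, input order breaks ties
        self._order = sorted(range(n), key=lambda r: (gen[r], r))

    # -- derived views ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def is_founder(self) -> np.ndarray:
        return self._father < 0

    @property
    def father_index(self) -> np.ndarray:
        """Row index of each individual's father, -1 for founders."""
        return self._father

    @property
    def mother_index(self) -> np.ndarray:
        return self._mother

    @property
    def generation(self) -> np.ndarray:
        return self._generation

    @property
    def topological_order(self) -> list[int]:
        return list(self._order)

    @property
    def sample_ids(self) -> list[str]:
        """Global sample ids: plain individual ids when unique, else family-qualified."""
        ids = self.table["individual_id"].tolist()
        if len(set(ids)) == len(ids):
            return ids
        return [f"{f}:{i}" for f, i in
                zip(self.table["family_id"], self.table["individual_id"])]

    @property
    def families(self) -> list[str]:
        seen, out = set(), []
        for f in self.table["family_id"]:
            if f not in seen:
                seen.add(f)
                out.append(f)
        return out

    def founder_ids(self) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.is_founder) if f]


# -- file I/O ---------------------------------------------------------

_LINKAGE_COLS = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
_SOLAR_COLS = {"famid": "family_id", "id": "individual_id",
               "fa": "father_id", "mo": "mother_id", "sex": "sex"}


def read_pedigree(path, dialect: str = "linkage") -> Pedigree:
    """Read a pedigree file.

    ``linkage``: whitespace-delimited, no header, columns fam/id/fa/mo/sex,
    missing parent "0", sex 1=male 2=female 0=unknown. ``solar-csv``:
    headered CSV with columns famid,id,fa,mo,sex.
    """
    if dialect == "linkage":
        t = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                        names=_LINKAGE_COLS, usecols=range(5))
    elif dialect == "solar-csv":
        t = pd.read_csv(path, dtype=str)
        t.columns = [c.strip().lower() for c in t.columns]
        missing = set(_SOLAR_COLS) - set(t.columns)
        if missing:
            raise PedigreeError(f"solar-csv pedigree missing columns {sorted(missing)}")
        t = t.rename(columns=_SOLAR_COLS)[_LINKAGE_COLS]
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    return Pedigree(t)


def write_pedigree(ped: Pedigree, path, dialect: str = "linkage") -> None:
    t = ped.table.copy()
    t["father_id"] = t["father_id"].fillna("0")
    t["mother_id"] = t["mother_id"].fillna("0")
    if dialect == "linkage":
        t["sex"] = t["sex"].map({MALE: "1", FEMALE: "2", UNKNOWN: "0"})
        t[_LINKAGE_COLS].to_csv(path, sep=" ", header=False, index=False)
    elif dialect == "solar-csv":
        out = t[_LINKAGE_COLS].rename(
            columns={v: k for k, v in _SOLAR_COLS.items()})
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")


# -- expected kinship -------------------------------------------------

def pedigree_kinship(ped: Pedigree) -> KinshipMatrix:
    """Expected relatedness (2Φ) for every pair of pedigree members.

    Runs the kinship recursion in parent-before-child order; members of
    genealogically unconnected families come out exactly 0. The result
    is positive semidefinite by construction.
    """
    n = ped.n
    fa, mo = ped.father_index, ped.mother_index
    phi = np.zeros((n, n))
    order = ped.topological_order
    done: list[int] = []
    for i in order:
        if fa[i] < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[fa[i], mo[i]])
            if done:
                prev = np.array(done)
                vals = 0.5 * (phi[fa[i], prev] + phi[mo[i], prev])
                phi[i, prev] = vals
                phi[prev, i] = vals
        done.append(i)
    return KinshipMatrix(sample_ids=ped.sample_ids, values=2.0 * phi,
                         source="pedigree")
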