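"""Pairwise relationship inference from genotypes.

A method-of-moments identity-by-descent (IBD) estimator in the style of
PLINK's ``--genome``: observed identity-by-state (IBS) counts are
compared with their expectations given allele frequencies to solve for
the proportions of the genome shared IBD-0/1/2, from which the
estimated kinship coefficient is φ̂ = ¼·IBD1 + ½·IBD2. Pairs are then
binned into relationship degrees at the standard power-of-two kinship
cutoffs, and the inferred classes are reconciled against the recorded
pedigree to flag likely sample swaps. The estimator assumes
approximately independent markers, so it should be run on an LD-pruned
panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, allele_frequencies
from .pedigree import Pedigree, pedigree_kinship

log = logging.getLogger(__name__)

__all__ = ["RelationshipCall", "moment_ibd", "moment_ibd_pairs",
           "classify_relationship", "expected_relationship",
           "pedigree_discordance", "DiscordanceReport"]

# kinship-coefficient (φ) class boundaries: 2^-1.5, 2^-2.5, 2^-3.5, 2^-4.5
KINSHIP_CUTOFFS = (0.354, 0.177, 0.0884, 0.0442)

MZ, PO, FS, SECOND, THIRD, UNREL = (
    "MZ/duplicate", "parent-offspring", "full-sibling",
    "2nd-degree", "3rd-degree", "unrelated")

MIN_INFORMATIVE_SNPS = 200


@dataclass
class RelationshipCall:
    id1: str
    id2: str
    ibd0: float
    ibd1: float
    ibd2: float
    kinship_hat: float
    inferred_class: str
    expected_class: str | None = None
    discordant: bool | None = None


def _simplex_project(raw: np.ndarray) -> np.ndarray:
    """Truncate negatives to 0 and renormalise rows to sum 1."""
    out = np.clip(raw, 0.0, None)
    s = out.sum(axis=-1, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    return out / s


def _expected_ibs_sums(p: np.ndarray) -> np.ndarray:
    """Σ_snps P(IBS=k | IBD=j); rows k=0..2, columns j=0..2."""
    q = 1 - p
    e = np.empty((3, 3))
    e[0, 0] = np.sum(2 * p ** 2 * q ** 2)
    e[1, 0] = np.sum(4 * p ** 3 * q + 4 * p * q ** 3)
    e[2, 0] = np.sum(p ** 4 + q ** 4 + 4 * p ** 2 * q ** 2)
    e[0, 1] = 0.0
    e[1, 1] = np.sum(2 * p ** 2 * q + 2 * p * q ** 2)
    e[2, 1] = np.sum(p ** 3 + q ** 3 + p ** 2 * q + p * q ** 2)
    e[0, 2] = 0.0
    e[1, 2] = 0.0
    e[2, 2] = float(len(p))
    return e


def _solve_moments(ibs_counts: np.ndarray, e: np.ndarray) -> np.ndarray:
    """PLINK-style sequential moment solve; rows of ibs_counts are pairs."""
    c = np.atleast_2d(ibs_counts).astype(float)
    ibd0 = c[:, 0] / e[0, 0] if e[0, 0] > 0 else np.zeros(len(c))
    ibd1 = (c[:, 1] - ibd0 * e[1, 0]) / e[1, 1] if e[1, 1] > 0 else np.zeros(len(c))
    ibd2 = (c[:, 2] - ibd0 * e[2, 0] - ibd1 * e[2, 1]) / e[2, 2]
    return _simplex_project(np.stack([ibd0, ibd1, ibd2], axis=1))


def moment_ibd(d1: np.ndarray, d2: np.ndarray, freqs: np.ndarray
               ) -> tuple[float, float, float, float]:
    """IBD-sharing proportions and kinship for one pair of dosage vectors.

    Uses pairwise-complete SNPs; raw estimates are projected onto the
    simplex {IBD ≥ 0, ΣIBD = 1}.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    freqs = np.asarray(freqs, float)
    ok = ~(np.isnan(d1) | np.isnan(d2)) & np.isfinite(freqs) \
        & (freqs > 0) & (freqs < 1)
    if ok.sum() == 0:
        raise ValueError("no jointly called SNPs for this pair")
    if ok.sum() < MIN_INFORMATIVE_SNPS:
        warnings.warn(f"only {int(ok.sum())} informative SNPs; "
                      "IBD estimates will be noisy", stacklevel=2)
    diff = np.abs(d1[ok] - d2[ok])
    counts = np.array([np.sum(diff == 2), np.sum(diff == 1), np.sum(diff == 0)])
    e = _expected_ibs_sums(freqs[ok])
    ibd = _solve_moments(counts, e)[0]
    kin = 0.25 * ibd[1] + 0.5 * ibd[2]
    return float(ibd[0]), float(ibd[1]), float(ibd[2]), float(kin)


def moment_ibd_pairs(g: GenotypeMatrix, pairs: list[tuple[str, str]],
                     freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorised moment-IBD over a list of sample-id pairs.

    Assumes (and is fastest with) complete genotypes; pairs with missing
    calls fall back to the per-pair path.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    informative = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    d = g.dosages[:, informative]
    p = freqs[informative]
    lookup = {s: i for i, s in enumerate(g.sample_ids)}
    i1 = np.array([lookup[a] for a, _ in pairs], dtype=int)
    i2 = np.array([lookup[b] for _, b in pairs], dtype=int)
    if np.isnan(d).any():
        rows = [moment_ibd(d[a], d[b], p) for a, b in zip(i1, i2)]
        ibd = np.array([r[:3] for r in rows])
        kin = np.array([r[3] for r in rows])
    else:
        e = _expected_ibs_sums(p)
        m = d.shape[1]
        counts = np.empty((len(pairs), 3))
        chunk = max(1, int(2e7) // max(m, 1))
        for start in range(0, len(pairs), chunk):
            sl = slice(start, start + chunk)
            diff = np.abs(d[i1[sl]] - d[i2[sl]])
            counts[sl, 0] = np.sum(diff == 2, axis=1)
            counts[sl, 1] = np.sum(diff == 1, axis=1)
            counts[sl, 2] = m - counts[sl, 0] - counts[sl, 1]
        ibd = _solve_moments(counts, e)
        kin = 0.25 * ibd[:, 1] + 0.5 * ibd[:, 2]
    return pd.DataFrame({
        "id1": [a for a, _ in pairs], "id2": [b for _, b in pairs],
        "ibd0": ibd[:, 0], "ibd1": ibd[:, 1], "ibd2": ibd[:, 2],
        "kinship_hat": kin,
        "inferred_class": [classify_relationship(*row, k)
                           for row, k in zip(ibd, kin)],
    })


def classify_relationship(ibd0: float, ibd1: float, ibd2: float,
                          kinship_hat: float) -> str:
    """Relationship degree from estimated kinship, with IBD0 splitting
    parent-offspring (IBD0 < 0.1) from full siblings in the 1st-degree band."""
    t = KINSHIP_CUTOFFS
    if kinship_hat >= t[0]:
        return MZ
    if kinship_hat >= t[1]:
        return PO if ibd0 < 0.1 else FS
    if kinship_hat >= t[2]:
        return SECOND
    if kinship_hat >= t[3]:
        return THIRD
    return UNREL


def expected_relationship(ped: Pedigree) -> pd.DataFrame:
    """Expected relationship class for every within-family pair.

    Derived from the pedigree kinship (2Φ) with the same degree bands the
    classifier uses; the parent/child split comes from the parent graph.
    """
    k = pedigree_kinship(ped)
    ids = ped.sample_ids
    fam = ped.table["family_id"].to_numpy()
    fa, mo = ped.father_index, ped.mother_index
    parent_pairs = set()
    sib_pairs = set()
    for i in range(ped.n):
        if fa[i] >= 0:
            parent_pairs.add(frozenset((i, fa[i])))
            parent_pairs.add(frozenset((i, mo[i])))
    for i in range(ped.n):
        for j in range(i + 1, ped.n):
            if fa[i] >= 0 and fa[i] == fa[j] and mo[i] == mo[j]:
                sib_pairs.add(frozenset((i, j)))
    rows = []
    phi2 = k.values
    for i in range(ped.n):
        for j in range(i + 1, ped.n):
            if fam[i] != fam[j]:
                continue
            v = phi2[i, j]
            if v >= 0.9:
                cls = MZ
            elif v >= 2 * KINSHIP_CUTOFFS[1]:
                cls = PO if frozenset((i, j)) in parent_pairs else FS
            elif v >= 2 * KINSHIP_CUTOFFS[2]:
                cls = SECOND
            elif v >= 2 * KINSHIP_CUTOFFS[3]:
                cls = THIRD
            else:
                cls = UNREL
            rows.append((ids[i], ids[j], v, cls))
    return pd.DataFrame(rows, columns=["id1", "id2", "two_phi", "expected_class"])


@dataclass
class DiscordanceReport:
    """Within-pedigree discordances plus the proposed exclusion list."""

    table: pd.DataFrame           # all within-pedigree calls, flagged
    cross_pedigree: pd.DataFrame  # cross-family pairs above the 3rd-degree bound
    proposed_exclusions: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pedigree_discordance(ped: Pedigree, calls: pd.DataFrame,
                         cross_calls: pd.DataFrame | None = None
                         ) -> DiscordanceReport:
    """Reconcile inferred relationships with the recorded genealogy.

    ``calls`` is the :func:`moment_ibd_pairs` output for within-family
    pairs. A pair is discordant when the inferred class differs from the
    class expected under the pedigree; the report also records how many
    relationship degrees apart the two classes are (``severity``), since
    the degree bands adjoin and a one-band flip near a boundary is
    expected estimator noise rather than evidence of a sample error.

    The proposed exclusion list targets the samples that explain the
    *strong* discordances (two or more degrees apart — e.g. a recorded
    1st-degree pair measured unrelated): within each family, any
    individual involved in two or more of them (a swapped sample breaks
    every one of its genotyped relationships at once); when a strong
    discordance cannot be attributed that way, both members are
    proposed, mirroring how irresolvable swaps are handled in practice.
    """
    expected = expected_relationship(ped)
    key = {frozenset((a, b)): c for a, b, c in
           zip(expected["id1"], expected["id2"], expected["expected_class"])}
    t = calls.copy()
    t["expected_class"] = [key.get(frozenset((a, b)), "cross-pedigree")
                           for a, b in zip(t["id1"], t["id2"])]
    t["discordant"] = (t["expected_class"] != "cross-pedigree") & \
        (t["expected_class"] != t["inferred_class"])
    degree = {MZ: 0, PO: 1, FS: 1, SECOND: 2, THIRD: 3, UNREL: 4}
    t["severity"] = [
        abs(degree[i] - degree[e]) if d else 0
        for i, e, d in zip(t["inferred_class"], t["expected_class"],
                           t["discordant"])]

    strong = t[t["severity"] >= 2]
    count: dict[str, int] = {}
    for a, b in zip(strong["id1"], strong["id2"]):
        count[a] = count.get(a, 0) + 1
        count[b] = count.get(b, 0) + 1
    proposed = {s for s, c in count.items() if c >= 2}
    for a, b in zip(strong["id1"], strong["id2"]):
        if a not in proposed and b not in proposed:
            proposed.update((a, b))

    if cross_calls is not None:
        cross = cross_calls[cross_calls["kinship_hat"] > KINSHIP_CUTOFFS[3]].copy()
    else:
        cross = pd.DataFrame(columns=calls.columns)
    order = {s: i for i, s in enumerate(ped.sample_ids)}
    return DiscordanceReport(
        table=t, cross_pedigree=cross,
        proposed_exclusions=sorted(proposed, key=lambda s: order.get(s, 1 << 30)))
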