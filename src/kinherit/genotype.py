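"""Genotype containers, text-format readers, and marker QC.

Dosages count copies of the alternate allele (0/1/2, NaN = missing).
QC mirrors a conventional array-data pipeline: alternate-allele
frequencies, a 1-df chi-square Hardy-Weinberg goodness-of-fit test, and
greedy windowed LD pruning of the kind done with
``--indep-pairwise <window> <step> <r2>``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "allele_frequencies",
    "hwe_test",
    "hwe_filter",
    "ld_prune",
]

_ACGT = set("ACGT")
_SNP_COLS = ["snp_id", "chrom", "pos", "ref", "alt"]


def _chrom_key(c: str):
    return (0, int(c)) if re.fullmatch(r"\d+", c) else (1, c)


@dataclass
class GenotypeMatrix:
    """Samples × SNPs alternate-allele dosage matrix with marker metadata.

    ``snps`` is a DataFrame with columns snp_id, chrom, pos (1-based),
    ref, alt; markers are kept sorted by (chrom, pos). ``dosages`` is a
    float array with entries in {0, 1, 2, NaN}.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        s = self.snps.reset_index(drop=True).copy()
        missing = set(_SNP_COLS) - set(s.columns)
        if missing:
            raise ValueError(f"snp table missing columns {sorted(missing)}")
        s["snp_id"] = s["snp_id"].astype(str)
        s["chrom"] = s["chrom"].astype(str)
        s["pos"] = s["pos"].astype(int)
        if s["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids")
        if (s["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        for col in ("ref", "alt"):
            bad = ~s[col].isin(_ACGT)
            if bad.any():
                raise ValueError(
                    f"non-ACGT {col} allele at snp {s.loc[bad.idxmax(), 'snp_id']}")
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.sample_ids), len(s)):
            raise ValueError(
                f"dosage shape {d.shape} != (samples={len(self.sample_ids)}, "
                f"snps={len(s)})")
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        key = s.apply(lambda r: (_chrom_key(r["chrom"]), r["pos"]), axis=1)
        order = np.argsort(key.to_numpy(), kind="stable") if len(s) else np.array([], int)
        self.snps = s.iloc[order].reset_index(drop=True)
        self.dosages = d[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        wanted = set(map(str, snp_ids))
        mask = self.snps["snp_id"].isin(wanted).to_numpy()
        return replace(self, snps=self.snps[mask], dosages=self.dosages[:, mask])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[str(s)] for s in ids]
        return replace(self, sample_ids=[str(s) for s in ids],
                       dosages=self.dosages[idx])

    # -- writers ------------------------------------------------------

    def write_ped_map(self, prefix) -> None:
        """Write whitespace PED (+6 leading columns) and 4-column MAP."""
        with open(f"{prefix}.map", "w") as fh:
            for r in self.snps.itertuples():
                fh.write(f"{r.chrom} {r.snp_id} 0 {r.pos}\n")
        with open(f"{prefix}.ped", "w") as fh:
            for i, sid in enumerate(self.sample_ids):
                cells = [sid, sid, "0", "0", "0", "-9"]
                for j, r in enumerate(self.snps.itertuples()):
                    d = self.dosages[i, j]
                    if np.isnan(d):
                        cells += ["0", "0"]
                    else:
                        alleles = [r.alt] * int(d) + [r.ref] * (2 - int(d))
                        cells += alleles
                fh.write(" ".join(cells) + "\n")

    def write_dosage_table(self, prefix) -> None:
        """Write a sample × SNP dosage TSV plus a 6-column marker map."""
        df = pd.DataFrame(self.dosages, columns=self.snps["snp_id"])
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(f"{prefix}.tsv", sep="\t", index=False, na_rep="NA")
        self.snps[["chrom", "snp_id", "pos", "ref", "alt"]].to_csv(
            f"{prefix}.map", sep="\t", index=False)


# -- readers ----------------------------------------------------------

def _read_ped_map(path) -> GenotypeMatrix:
    prefix = re.sub(r"\.(ped|map)$", "", str(path))
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None, dtype=str,
                     names=["chrom", "snp_id", "cm", "pos"])
    rows = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            cells = line.split()
            if cells:
                rows.append(cells)
    m = len(mp)
    sample_ids, geno = [], []
    for cells in rows:
        if len(cells) != 6 + 2 * m:
            raise ValueError(
                f"PED row for sample {cells[1]} has {len(cells) - 6} allele "
                f"columns; MAP declares {m} SNPs")
        sample_ids.append(cells[1])
        geno.append(cells[6:])
    alleles = np.array(geno, dtype="U1").reshape(len(rows), m, 2)
    ref = np.empty(m, dtype="U1")
    alt = np.empty(m, dtype="U1")
    dos = np.full((len(rows), m), np.nan)
    for j in range(m):
        a = alleles[:, j, :]
        obs = a[a != "0"]
        uniq = sorted(set(obs.tolist()))
        if not set(uniq).issubset(_ACGT):
            raise ValueError(f"non-ACGT allele {set(uniq) - _ACGT} at SNP "
                             f"{mp.at[j, 'snp_id']}")
        if len(uniq) > 2:
            raise ValueError(f"SNP {mp.at[j, 'snp_id']} has >2 alleles")
        if not uniq:
            ref[j], alt[j] = "A", "C"  # fully missing column
            continue
        if len(uniq) == 1:
            ref[j] = uniq[0]
            alt[j] = next(b for b in "ACGT" if b != ref[j])
        else:
            # alternate allele = minor allele; lexicographic on ties
            counts = {u: int(np.sum(obs == u)) for u in uniq}
            uniq = sorted(uniq, key=lambda u: (-counts[u], u))
            ref[j], alt[j] = uniq[0], uniq[1]
        called = a[:, 0] != "0"
        dos[called, j] = (a[called] == alt[j]).sum(axis=1)
    snps = pd.DataFrame({"snp_id": mp["snp_id"], "chrom": mp["chrom"],
                         "pos": mp["pos"].astype(int), "ref": ref, "alt": alt})
    return GenotypeMatrix(sample_ids, snps, dos)


def _read_dosage_table(path) -> GenotypeMatrix:
    prefix = re.sub(r"\.(tsv|csv)$", "", str(path))
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    snp_ids = [c for c in df.columns if c != "sample_id"]
    try:
        mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", dtype=str)
        mp["pos"] = mp["pos"].astype(int)
        meta = mp.set_index("snp_id").loc[snp_ids]
        snps = pd.DataFrame({"snp_id": snp_ids, "chrom": meta["chrom"].tolist(),
                             "pos": meta["pos"].tolist(), "ref": meta["ref"].tolist(),
                             "alt": meta["alt"].tolist()})
    except FileNotFoundError:
        snps = pd.DataFrame({"snp_id": snp_ids, "chrom": "1",
                             "pos": np.arange(1, len(snp_ids) + 1),
                             "ref": "A", "alt": "C"})
    return GenotypeMatrix(df["sample_id"].tolist(), snps,
                          df[snp_ids].to_numpy(float))


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    recs, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not (v.REF in _ACGT and v.ALT[0] in _ACGT):
            n_multi += 1
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        recs.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM).removeprefix("chr"),
                     v.POS, v.REF, v.ALT[0]))
        cols.append(d)
    if n_multi:
        log.info("skipped %d multi-allelic/non-SNP VCF records", n_multi)
    snps = pd.DataFrame(recs, columns=_SNP_COLS)
    dos = np.array(cols).T if cols else np.empty((len(sample_ids), 0))
    g = GenotypeMatrix(sample_ids, snps, dos)
    g.n_skipped = n_multi  # type: ignore[attr-defined]
    return g


def read_genotypes(path, format: str = "ped") -> GenotypeMatrix:
    """Load genotypes from ``ped`` (+map), ``dosage`` table, or ``vcf``."""
    readers = {"ped": _read_ped_map, "ped+map": _read_ped_map,
               "dosage": _read_dosage_table, "dosage-table": _read_dosage_table,
               "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    return readers[format](path)


# -- QC ---------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per SNP; NaN where every call is missing."""
    d = g.dosages
    n_called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, np.nansum(d, axis=0) / (2.0 * n_called), np.nan)
    if np.any(n_called == 0):
        log.warning("%d SNPs have no called genotypes; frequency undefined",
                    int(np.sum(n_called == 0)))
    return freq


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p-value against p², 2pq, q².

    Allele frequency is taken from the same counts; a monomorphic SNP
    returns p = 1 (no departure is testable).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("no genotype calls")
    q = (n_het + 2 * n_hom_alt) / (2.0 * n)
    p = 1.0 - q
    if q <= 0.0 or q >= 1.0:
        return 1.0
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_filter(g: GenotypeMatrix, threshold: float = 0.05) -> list[str]:
    """SNP ids whose HWE p-value is >= ``threshold`` (the survivors)."""
    d = g.dosages
    keep = []
    for j, sid in enumerate(g.snps["snp_id"]):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = (int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
        if hwe_test(*counts) >= threshold:
            keep.append(sid)
    return keep


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(g: GenotypeMatrix, window_snps: int = 2000, step_snps: int = 10,
             r2_threshold: float = 0.1) -> list[str]:
    """Greedy windowed LD pruning; returns the retained snp_id list.

    Each SNP, in map order and per chromosome, is compared against the
    retained SNPs within the trailing ``window_snps``-wide window; when a
    pair exceeds ``r2_threshold`` the member with the lower minor-allele
    frequency is dropped (input order breaks ties). The window slides
    per variant, which is at least as strict as advancing it by
    ``step_snps`` at a time, so the retained set never contains a
    within-window pair above the threshold and re-pruning it is a no-op.
    """
    if not (window_snps >= step_snps >= 1):
        raise ValueError("need window_snps >= step_snps >= 1")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    freqs = allele_frequencies(g)
    maf = np.minimum(freqs, 1 - freqs)
    d = g.dosages
    has_missing = bool(np.isnan(d).any())
    retained: list[str] = []
    for chrom in g.snps["chrom"].unique():
        idx = np.flatnonzero((g.snps["chrom"] == chrom).to_numpy())
        kept: list[int] = []  # positions within idx
        if not has_missing:
            cols = d[:, idx]
            mu = cols.mean(axis=0)
            sd = cols.std(axis=0)
            z = np.where(sd > 0, (cols - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        for a, j in enumerate(idx):
            if np.isnan(freqs[j]) or maf[j] == 0:
                continue  # uninformative; drop from the pruned panel
            drop = False
            window = [b for b in kept if a - b < window_snps]
            if window and not has_missing:
                r2 = (z[:, window].T @ z[:, a] / g.n_samples) ** 2
            for w, b in enumerate(window):
                r2_ab = r2[w] if not has_missing else _pairwise_r2(d[:, idx[b]], d[:, j])
                if r2_ab > r2_threshold:
                    # remove the lower-MAF member of the pair
                    if maf[j] < maf[idx[b]]:
                        drop = True
                        break
                    kept.remove(b)
            if not drop:
                kept.append(a)
        retained.extend(g.snps["snp_id"].iloc[idx[kept]].tolist())
    return retained
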