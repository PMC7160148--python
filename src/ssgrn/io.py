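"""Pedigree and genotype containers plus the text formats the pipeline reads.

Internal conventions: coordinates are 1-based inclusive, genotype calls are
additive dosages of the counted allele in {0, 1, 2} with -1 for missing, and
pedigrees are kept topologically ordered (parents before offspring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``sire``/``dam`` hold positional indices into ``ids`` (-1 = unknown).
    ``meta`` optionally carries per-animal attributes (sex, generation,
    contemporary group) produced by the simulator.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    meta: pd.DataFrame | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate animal ids: {list(dup[dup > 1].index[:5])}"
            )
        for i in range(self.n):
            for p in (self.sire[i], self.dam[i]):
                if p >= i:
                    raise PedigreeError(
                        f"pedigree not topologically ordered at animal {self.ids[i]!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animals) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animals], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"animal {e.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return np.where(idx >= 0, self.ids[np.clip(idx, 0, None)], "0")

        return pd.DataFrame(
            {"animal": self.ids, "sire": name(self.sire), "dam": name(self.dam)}
        )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an ``animal,sire,dam`` CSV and return a topologically ordered pedigree.

    Unknown parents are coded ``0`` or left empty.  Parents referenced but not
    listed as animals are added as founders.  Cycles (an animal among its own
    ancestors) are rejected.
    """
    df = pd.read_csv(path, dtype=str).fillna("0")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file missing column {col!r}")
    animals = df["animal"].tolist()
    if len(set(animals)) != len(animals):
        dup = pd.Series(animals).value_counts()
        raise PedigreeError(f"duplicate animal ids: {list(dup[dup > 1].index[:5])}")
    parents = {}
    for _, row in df.iterrows():
        parents[row["animal"]] = (
            row["sire"] if row["sire"] != "0" else None,
            row["dam"] if row["dam"] != "0" else None,
        )
    # implicit founders: parents never listed as animals
    known = set(parents)
    implicit = []
    for s, d in list(parents.values()):
        for p in (s, d):
            if p is not None and p not in known:
                implicit.append(p)
                known.add(p)
    for p in implicit:
        parents[p] = (None, None)

    # Kahn topological sort, stable in input order
    order: list[str] = []
    placed: set[str] = set()
    pending = implicit + animals
    while pending:
        progressed = False
        remaining = []
        for a in pending:
            s, d = parents[a]
            if (s is None or s in placed) and (d is None or d in placed):
                order.append(a)
                placed.add(a)
                progressed = True
            else:
                remaining.append(a)
        if not progressed:
            raise PedigreeError(
                f"pedigree cycle detected involving animal {remaining[0]!r}"
            )
        pending = remaining

    idx = {a: i for i, a in enumerate(order)}
    sire = np.array([idx[parents[a][0]] if parents[a][0] else -1 for a in order])
    dam = np.array([idx[parents[a][1]] if parents[a][1] else -1 for a in order])
    return Pedigree(np.array(order, dtype=object), sire, dam)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls as counted-allele dosages over an ordered animal set."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray  # (n_animals, n_snps) int8, -1 missing

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions decrease within chromosome {c}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP from non-missing calls (NaN if all missing)."""
        obs = self.calls >= 0
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, self.calls, 0).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, p, np.nan)

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=1)

    def dosage_matrix(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Float dosages with missing calls mean-imputed to 2p (never persisted)."""
        p = self.allele_freq if freqs is None else np.asarray(freqs, dtype=float)
        d = self.calls.astype(float)
        miss = self.calls < 0
        if miss.any():
            d[miss] = np.broadcast_to(2.0 * p, d.shape)[miss]
        return d

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        ai = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            self.animal_ids[ai],
            self.snp_ids[si],
            self.chrom[si],
            self.pos[si],
            self.calls[np.ix_(ai, si)],
        )


def _read_map(path: Path):
    m = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if m.shape[1] < 4:
        raise ValueError(f"map file {path} needs 4 columns (chrom, snp, cM, pos)")
    return m[0].to_numpy(), m[1].to_numpy(dtype=object), m[3].to_numpy(dtype=np.int64)


def read_genotypes(
    path: str | Path,
    dialect: str = "raw_additive",
    pedigree: Pedigree | None = None,
) -> GenotypeMatrix | tuple[GenotypeMatrix, list[str]]:
    """Read genotypes in a PLINK text dialect.

    ``ped_map`` expects a ``.ped`` file (with a sibling ``.map``) holding two
    allele columns per SNP; calls are recoded as minor-allele dosage and a
    site with more than two alleles is an error.  ``raw_additive`` expects a
    ``.raw``-style additive table (counted-allele dosage 0/1/2, NA missing)
    with a sibling ``.map`` for coordinates when available.

    When ``pedigree`` is given, a list of genotyped ids absent from it is
    returned alongside the matrix.
    """
    path = Path(path)
    if dialect == "ped_map":
        geno = _read_ped_map(path)
    elif dialect == "raw_additive":
        geno = _read_raw(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if pedigree is not None:
        known = set(pedigree.ids)
        orphans = [a for a in geno.animal_ids if a not in known]
        if orphans:
            warnings.warn(f"{len(orphans)} genotyped animals absent from pedigree")
        return geno, orphans
    return geno


def _read_ped_map(path: Path) -> GenotypeMatrix:
    chrom, snp_ids, pos = _read_map(path.with_suffix(".map"))
    rows = []
    ids = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            ids.append(tok[1])
            rows.append(tok[6:])
    alleles = np.array(rows, dtype=object)  # (n, 2m)
    if alleles.shape[1] != 2 * len(snp_ids):
        raise ValueError(
            f"{path}: {alleles.shape[1] // 2} genotype pairs but map lists {len(snp_ids)} SNPs"
        )
    n, m = len(ids), len(snp_ids)
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for k in range(m):
        obs = np.unique(np.concatenate([a1[:, k], a2[:, k]]))
        obs = [x for x in obs if x != "0"]
        if len(obs) > 2:
            raise ValueError(f"SNP {snp_ids[k]} is not biallelic: alleles {obs}")
        if not obs:
            continue
        # count the rarer allele; deterministic alphabetical tie-break
        counts = {al: int(np.sum(a1[:, k] == al) + np.sum(a2[:, k] == al)) for al in obs}
        minor = sorted(obs, key=lambda al: (counts[al], al))[0]
        miss = (a1[:, k] == "0") | (a2[:, k] == "0")
        calls[:, k] = (a1[:, k] == minor).astype(np.int8) + (a2[:, k] == minor)
        calls[miss, k] = MISSING
    return GenotypeMatrix(np.array(ids, dtype=object), snp_ids, chrom, pos, calls)


def _read_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError(f"{path}: .raw header must contain IID")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    ids = df["IID"].astype(str).to_numpy(dtype=object)
    calls = df[snp_cols].to_numpy(dtype=float)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    if not np.all(np.isin(out, [MISSING, 0, 1, 2])):
        raise ValueError(f"{path}: additive calls must be 0/1/2 or NA")
    snp_ids = np.array([c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols], dtype=object)
    mp = path.with_suffix(".map")
    if mp.exists():
        chrom, map_ids, pos = _read_map(mp)
        if list(map_ids) != list(snp_ids):
            raise ValueError(f"{mp}: SNP ids disagree with .raw header")
    else:
        chrom = np.zeros(len(snp_ids), dtype=np.int64)
        pos = np.arange(1, len(snp_ids) + 1, dtype=np.int64)
    return GenotypeMatrix(ids, snp_ids, chrom, pos, out)


def write_genotypes(geno: GenotypeMatrix, path: str | Path, dialect: str = "raw_additive") -> None:
    """Write genotypes (plus a sibling ``.map``) in the named dialect."""
    path = Path(path)
    mp = path.with_suffix(".map")
    pd.DataFrame(
        {"chrom": geno.chrom, "snp": geno.snp_ids, "cm": 0, "pos": geno.pos}
    ).to_csv(mp, sep="\t", header=False, index=False)
    if dialect == "raw_additive":
        cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        head = " ".join(cols + [f"{s}_B" for s in geno.snp_ids])
        with open(path, "w") as fh:
            fh.write(head + "\n")
            for i, a in enumerate(geno.animal_ids):
                row = geno.calls[i].astype(object)
                vals = ["NA" if v == MISSING else str(int(v)) for v in row]
                fh.write(f"0 {a} 0 0 0 -9 " + " ".join(vals) + "\n")
    elif dialect == "ped_map":
        # allele A = reference, allele B = counted; dosage = #B
        pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
        with open(path, "w") as fh:
            for i, a in enumerate(geno.animal_ids):
                geno_str = " ".join(pair[int(v)] for v in geno.calls[i])
                fh.write(f"0 {a} 0 0 0 -9 {geno_str}\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV with at least animal, cg and a trait value column."""
    df = pd.read_csv(path, dtype={"animal": str, "cg": str})
    need = {"animal", "cg", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(need)}")
    return df
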