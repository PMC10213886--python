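"""Core data containers shared by every pipeline stage.

Genotypes are reference-allele dosages coded 0/1/2 with ``-1`` for missing,
stored as a dense ``int8`` matrix (individuals x SNPs).  Marker maps use
1-based base-pair coordinates, PLINK MAP convention.  Pedigrees are
two-generation tables (id, sire, dam) with ``"0"`` marking an unknown parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with row/column identifiers."""

    def __init__(self, dosages: np.ndarray, ids: list[str], snps: list[str]):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if dosages.shape != (len(ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(ids)} ids x {len(snps)} snps"
            )
        bad = ~np.isin(dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        self.dosages = dosages
        self.ids = list(map(str, ids))
        self.snps = list(map(str, snps))
        self._id_index = {s: i for i, s in enumerate(self.ids)}
        self._snp_index = {s: i for i, s in enumerate(self.snps)}

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def id_indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._id_index[str(i)] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def snp_indices(self, snps) -> np.ndarray:
        try:
            return np.array([self._snp_index[str(s)] for s in snps], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown SNP id {e.args[0]!r}") from None

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    # -------------------------------------------------------------- statistics
    def allele_freq(self) -> np.ndarray:
        """Per-SNP reference-allele frequency over non-missing genotypes.

        Monomorphic-missing columns (no calls) return NaN.
        """
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def ind_missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=1)

    # ----------------------------------------------------------------- subsets
    def subset(self, ids=None, snps=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if ids is None else self.id_indices(ids)
        cols = np.arange(self.n_snps) if snps is None else self.snp_indices(snps)
        return GenotypeMatrix(
            self.dosages[np.ix_(rows, cols)],
            [self.ids[r] for r in rows],
            [self.snps[c] for c in cols],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.ids), list(self.snps))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_snps} SNPs)"


class MarkerMap:
    """Ordered SNP records (id, chromosome, bp position).

    Ordering is by chromosome (input order of first appearance) then strictly
    increasing position; duplicate ids or non-increasing positions within a
    chromosome are rejected.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"snp", "chrom", "pos"}
        if not required.issubset(table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        df = table[["snp", "chrom", "pos"]].copy()
        df["snp"] = df["snp"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if df["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in marker map")
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based bp)")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, snps, chroms, positions) -> "MarkerMap":
        return cls(pd.DataFrame({"snp": snps, "chrom": chroms, "pos": positions}))

    @property
    def snps(self) -> list[str]:
        return self.table["snp"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slices(self) -> dict[str, np.ndarray]:
        """Column indices per chromosome, in map order."""
        return {
            str(c): sub.index.to_numpy()
            for c, sub in self.table.groupby("chrom", sort=False)
        }

    def chrom_length_bp(self) -> dict[str, int]:
        """Chromosome length taken as the bp position of its last mapped SNP."""
        return {
            str(c): int(sub["pos"].iloc[-1])
            for c, sub in self.table.groupby("chrom", sort=False)
        }

    def subset(self, snps) -> "MarkerMap":
        keep = set(map(str, snps))
        return MarkerMap(self.table[self.table["snp"].isin(keep)])


@dataclass
class Pedigree:
    """Two-generation pedigree: id -> (sire, dam), '0' = unknown."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"id", "sire", "dam"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        df = self.table[["id", "sire", "dam"]].astype(str)
        if df["id"].duplicated().any():
            raise ValueError("duplicate ids in pedigree")
        known = set(df["id"])
        for col in ("sire", "dam"):
            bad = df.loc[(df[col] != "0") & ~df[col].isin(known), col]
            if len(bad):
                raise ValueError(f"{col} {bad.iloc[0]!r} not in pedigree ids")
        order = {i: k for k, i in enumerate(df["id"])}
        for _, row in df.iterrows():
            for p in (row["sire"], row["dam"]):
                if p != "0" and order[p] >= order[row["id"]]:
                    raise ValueError(f"parent {p} listed after offspring {row['id']}")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        return cls(pd.DataFrame(records, columns=["id", "sire", "dam"]))

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def parents_of(self, ind: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == str(ind)]
        if row.empty:
            raise KeyError(f"{ind!r} not in pedigree")
        return row["sire"].iloc[0], row["dam"].iloc[0]

    def founders(self) -> list[str]:
        t = self.table
        return t.loc[(t["sire"] == "0") & (t["dam"] == "0"), "id"].tolist()

    def offspring(self) -> list[str]:
        t = self.table
        return t.loc[(t["sire"] != "0") | (t["dam"] != "0"), "id"].tolist()

    def trios(self) -> list[tuple[str, str, str]]:
        """(offspring, sire, dam) for individuals with both parents known."""
        t = self.table
        both = t.loc[(t["sire"] != "0") & (t["dam"] != "0")]
        return list(both.itertuples(index=False, name=None))


class PhasedHaplotypes:
    """Per-individual pair of allele sequences: array (n_ind, 2, n_snps) of 0/1."""

    def __init__(self, haps: np.ndarray, ids: list[str], snps: list[str]):
        haps = np.asarray(haps, dtype=np.int8)
        if haps.ndim != 3 or haps.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_ind, 2, n_snps)")
        if haps.shape[0] != len(ids) or haps.shape[2] != len(snps):
            raise ValueError("haplotype shape does not match ids/snps")
        if not np.isin(haps, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        self.haps = haps
        self.ids = list(map(str, ids))
        self.snps = list(map(str, snps))
        self._id_index = {s: i for i, s in enumerate(self.ids)}

    def of(self, ind: str) -> np.ndarray:
        return self.haps[self._id_index[str(ind)]]

    def to_genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.haps.sum(axis=1), self.ids, self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)


@dataclass
class EvaluationReport:
    """Per-panel-density accuracy records, long format.

    Columns: method, density, imputation, metric, mean, sd, n.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["method", "density", "imputation", "metric", "mean", "sd", "n"]
        )
    )

    def add(self, method, density, imputation, metric, mean, sd, n) -> None:
        row = pd.DataFrame(
            [
                {
                    "method": method,
                    "density": int(density),
                    "imputation": imputation,
                    "metric": metric,
                    "mean": float(mean),
                    "sd": float(sd),
                    "n": int(n),
                }
            ]
        )
        if self.table.empty:
            self.table = row
        else:
            self.table = pd.concat([self.table, row], ignore_index=True)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
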