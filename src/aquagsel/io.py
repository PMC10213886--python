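"""File-format round-trips: VCF, PLINK PED/MAP, pedigree and phenotype TSV.

VCF is written as plain text (phased ``GT`` when haplotypes are available)
and read back through :mod:`cyvcf2`.  PED/MAP follow the PLINK 1.x text
dialect with alleles ``A`` (reference) / ``B`` (alternate) and ``0 0`` for a
missing genotype.  All tabular side files are tab-separated with headers.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap, Pedigree, PhasedHaplotypes

# --------------------------------------------------------------------- VCF


def write_vcf(
    path,
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    haps: PhasedHaplotypes | None = None,
) -> None:
    """Write genotypes (and optional phased haplotypes) to an uncompressed VCF.

    REF/ALT are placeholder ``A``/``B`` alleles; the dosage counts the
    reference allele, so dosage 2 is written ``0|0`` (two REF copies).
    """
    if marker_map.snps != geno.snps:
        raise ValueError("marker map and genotype SNP sets differ")
    hap_ids = set(haps.ids) if haps is not None else set()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in marker_map.chrom_length_bp().items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.ids)
            + "\n"
        )
        table = marker_map.table
        for j in range(geno.n_snps):
            chrom, pos, snp = table["chrom"][j], table["pos"][j], table["snp"][j]
            fields = [str(chrom), str(pos), snp, "A", "B", ".", "PASS", ".", "GT"]
            col = geno.dosages[:, j]
            for i, ind in enumerate(geno.ids):
                d = col[i]
                if d == MISSING:
                    fields.append("./.")
                elif haps is not None and ind in hap_ids:
                    h = haps.of(ind)[:, j]
                    # haplotype allele 1 = reference carried -> VCF allele 0
                    fields.append(f"{1 - h[0]}|{1 - h[1]}")
                else:
                    fields.append(["1/1", "0/1", "0/0"][d])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[GenotypeMatrix, MarkerMap, PhasedHaplotypes | None]:
    """Read a biallelic VCF; returns haplotypes when every call is phased."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps, chroms, positions = [], [], []
    dosage_rows, hap_rows = [], []
    all_phased = True
    for k, var in enumerate(vcf):
        snps.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        gts = var.genotype.array()  # (n, 3): allele0, allele1, phased flag
        a = gts[:, :2]
        miss = (a < 0).any(axis=1)
        # VCF allele 0 is REF; dosage counts REF copies
        dos = (a == 0).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        dosage_rows.append(dos)
        if all_phased and (miss.any() or not gts[:, 2].all()):
            all_phased = False
        hap_rows.append((a == 0).astype(np.int8))
    vcf.close()
    dosages = np.stack(dosage_rows, axis=1)
    mmap = MarkerMap.from_arrays(snps, chroms, positions)
    geno = GenotypeMatrix(dosages, ids, mmap.snps)
    haps = None
    if all_phased:
        haps = PhasedHaplotypes(np.stack(hap_rows, axis=2), ids, mmap.snps)
    return geno, mmap, haps


# ---------------------------------------------------------------- PED / MAP

_PED_CODES = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}


def write_ped_map(
    prefix, geno: GenotypeMatrix, marker_map: MarkerMap, ped: Pedigree | None = None
) -> None:
    """Write PLINK text PED/MAP (<prefix>.ped, <prefix>.map)."""
    if marker_map.snps != geno.snps:
        raise ValueError("marker map and genotype SNP sets differ")
    parents = {}
    if ped is not None:
        parents = {r[0]: (r[1], r[2]) for r in ped.table.itertuples(index=False)}
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in enumerate(geno.ids):
            sire, dam = parents.get(ind, ("0", "0"))
            alleles = " ".join(_PED_CODES[int(d)] for d in geno.dosages[i])
            fh.write(f"FAM {ind} {sire} {dam} 0 -9 {alleles}\n")
    with open(f"{prefix}.map", "w") as fh:
        for row in marker_map.table.itertuples(index=False):
            fh.write(f"{row.chrom} {row.snp} 0 {row.pos}\n")


def read_ped_map(prefix) -> tuple[GenotypeMatrix, MarkerMap]:
    map_df = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype=str,
    )
    mmap = MarkerMap.from_arrays(
        map_df["snp"], map_df["chrom"], map_df["pos"].astype(int)
    )
    ids, rows = [], []
    decode = {("A", "A"): 2, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 0, ("0", "0"): MISSING}
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * mmap.n_snps:
                raise ValueError(f"PED line for {parts[1]} has wrong allele count")
            pairs = zip(alleles[0::2], alleles[1::2])
            try:
                rows.append([decode[p] for p in pairs])
            except KeyError as e:
                raise ValueError(f"unknown allele code {e.args[0]}") from None
    return GenotypeMatrix(np.array(rows, dtype=np.int8), ids, mmap.snps), mmap


# -------------------------------------------------------------- TSV helpers


def write_pedigree_tsv(path, ped: Pedigree) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))


def write_phenotypes_tsv(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["id"] = df["id"].astype(str)
    return df


def write_panel(path, snp_ids) -> None:
    """One SNP id per line (PLINK --extract dialect)."""
    with open(path, "w") as fh:
        for s in snp_ids:
            fh.write(f"{s}\n")


def read_panel(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_genotypes(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Dispatch on extension: ``.vcf`` or a PED/MAP prefix."""
    path = str(path)
    if path.endswith(".vcf"):
        geno, mmap, _ = read_vcf(path)
        return geno, mmap
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    if os.path.exists(f"{prefix}.ped"):
        return read_ped_map(prefix)
    raise FileNotFoundError(f"no VCF or PED/MAP found at {path!r}")
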