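"""Synthetic two-generation aquaculture populations.

The generator emulates the structure genomic-selection studies in farmed
fish and shellfish rely on: a small broodstock of HD-genotyped parents, a
few dozen to a couple of hundred large full-sib families, dense biallelic
SNP maps, and traits with moderate genomic heritability.

Founder haplotypes are mosaics of a small pool of ancestral haplotypes
(geometric segment lengths, one switch-rate knob controlling LD).  Offspring
are produced by gene-drop down the pedigree with Haldane (no-interference)
recombination.  Phenotypes follow ``y = mu + Xb + Za + e`` with QTL effects
rescaled to hit the target heritability exactly on the realized sample;
binary traits are thresholded liabilities.

All randomness flows from one root seed through named substreams, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, Pedigree, PhasedHaplotypes


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named, collision-resistant child stream of a root seed."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))


# ------------------------------------------------------------------- specs


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome pair: physical length, genetic length, marker count."""

    name: str
    length_bp: int
    n_snps: int
    genetic_length_cM: float | None = None  # None -> 1 cM/Mb default

    def __post_init__(self):
        if self.n_snps < 2:
            raise ValueError("each chromosome needs >= 2 SNPs")
        if self.length_bp < self.n_snps:
            raise ValueError("length_bp too short for n_snps distinct positions")
        if self.genetic_length_cM is not None and self.genetic_length_cM < 0:
            raise ValueError("genetic length must be non-negative")

    @property
    def cM(self) -> float:
        if self.genetic_length_cM is None:
            return self.length_bp / 1e6  # 1 cM/Mb
        return self.genetic_length_cM


@dataclass(frozen=True)
class PopulationDesign:
    """Broodstock mating design: sires x dams -> full-sib families."""

    n_sires: int
    n_dams: int
    n_families: int
    offspring_per_family: int
    mating: str = "factorial"  # or "monogamous"

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.n_families, self.offspring_per_family) < 1:
            raise ValueError("design counts must be positive")
        if self.n_families > self.n_sires * self.n_dams:
            raise ValueError("more families than sire x dam pairs")
        if self.mating == "monogamous" and self.n_families > min(self.n_sires, self.n_dams):
            raise ValueError("monogamous mating needs n_families <= min(sires, dams)")
        if self.mating not in ("factorial", "monogamous"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")


@dataclass(frozen=True)
class FixedEffectSpec:
    """Categorical fixed effect: levels assigned uniformly, effects N(0, sd^2)."""

    name: str
    n_levels: int
    sd: float


@dataclass(frozen=True)
class TraitModel:
    h2_target: float
    n_qtl: int
    trait_type: str = "continuous"  # or "binary"
    prevalence: float | None = None
    fixed_effects: tuple[FixedEffectSpec, ...] = ()

    def __post_init__(self):
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must be in (0,1)")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be positive")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError("binary trait needs prevalence strictly in (0,1)")


@dataclass
class SimOutput:
    """Truth set for one simulated population."""

    haplotypes: PhasedHaplotypes  # all individuals, truth phase
    genotypes: GenotypeMatrix  # possibly with genotyping error applied
    pedigree: Pedigree
    marker_map: MarkerMap
    chromosomes: tuple[ChromosomeSpec, ...]
    parent_ids: list[str]
    offspring_ids: list[str]
    phenotypes: pd.DataFrame | None = None
    true_bv: pd.Series | None = None
    qtl: pd.DataFrame | None = None
    seed: int | None = None


# ------------------------------------------------------------- marker maps


def build_marker_map(
    chromosomes: list[ChromosomeSpec],
    seed: int,
    clustering: float = 0.3,
) -> MarkerMap:
    """Draw strictly increasing SNP positions along each chromosome.

    Positions are clustered, emulating the uneven marker coverage of
    RAD-seq and array genotyping: cluster centres are uniform, cluster
    weights Dirichlet(``clustering``) (small values concentrate markers in
    few clusters), and markers scatter around their centre with a Laplace
    kernel.  ``clustering = 0`` disables clustering (uniform positions).
    """
    rng = substream(seed, "map")
    snps, chroms, positions = [], [], []
    for spec in chromosomes:
        n, L = spec.n_snps, spec.length_bp
        if clustering <= 0:
            raw = rng.integers(1, L + 1, size=3 * n + 100)
        else:
            k = max(4, n // 25)
            centers = rng.integers(1, L + 1, size=k)
            weights = rng.dirichlet(np.full(k, clustering))
            assign = rng.choice(k, size=3 * n, p=weights)
            raw = centers[assign] + np.round(rng.laplace(0.0, L / (8 * k), size=3 * n))
            raw = np.clip(raw, 1, L).astype(np.int64)
        pos = np.unique(raw)
        while len(pos) < n:
            extra = rng.integers(1, L + 1, size=n)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        for j, p in enumerate(pos):
            snps.append(f"{spec.name}_snp{j + 1}")
            chroms.append(spec.name)
            positions.append(int(p))
    return MarkerMap.from_arrays(snps, chroms, positions)


# ---------------------------------------------------------------- founders


def _resolve_maf_law(maf_law, rng, n):
    """Per-SNP reference-allele frequencies from a distribution spec."""
    if callable(maf_law):
        p = np.asarray(maf_law(rng, n), dtype=float)
    elif isinstance(maf_law, (int, float)):
        p = np.full(n, float(maf_law))
    else:
        kind = maf_law[0]
        if kind == "uniform":
            lo, hi = maf_law[1], maf_law[2]
            p = rng.uniform(lo, hi, size=n)
        elif kind == "beta":
            p = rng.beta(maf_law[1], maf_law[2], size=n)
        else:
            raise ValueError(f"unknown maf_law {maf_law!r}")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequencies must be strictly in (0,1)")
    return p


def simulate_founders(
    chromosomes: list[ChromosomeSpec],
    n_founders: int,
    n_ancestral: int,
    switch_rate: float,
    maf_law,
    seed: int,
    marker_map: MarkerMap | None = None,
    founder_ids: list[str] | None = None,
) -> tuple[PhasedHaplotypes, MarkerMap]:
    """Founder haplotypes as ancestral-haplotype mosaics.

    Each of the ``2 * n_founders`` founder haplotypes copies one of
    ``n_ancestral`` ancestral haplotypes, switching ancestor between adjacent
    SNPs with probability ``1 - exp(-switch_rate * gap_bp)`` (geometric
    segment lengths in bp).  ``switch_rate`` tunes founder LD: 0 gives exact
    ancestral copies, large values give free recombination.
    """
    if not np.isfinite(switch_rate) or switch_rate < 0:
        raise ValueError("switch_rate must be finite and >= 0")
    if n_ancestral < 2:
        raise ValueError("need at least 2 ancestral haplotypes")
    if marker_map is None:
        marker_map = build_marker_map(chromosomes, seed)
    rng = substream(seed, "founders")
    n_haps = 2 * n_founders
    slices = marker_map.chrom_slices()
    positions = marker_map.table["pos"].to_numpy()
    hap_chunks = []
    for spec in chromosomes:
        idx = slices[spec.name]
        m = len(idx)
        p = _resolve_maf_law(maf_law, rng, m)
        ancestral = (rng.random((n_ancestral, m)) < p).astype(np.int8)
        gaps = np.diff(positions[idx]).astype(float)
        p_switch = 1.0 - np.exp(-switch_rate * gaps)
        switches = rng.random((n_haps, m - 1)) < p_switch
        seg_id = np.concatenate(
            [np.zeros((n_haps, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
        )
        max_seg = int(seg_id.max()) + 1
        seg_anc = rng.integers(0, n_ancestral, size=(n_haps, max_seg))
        anc_idx = np.take_along_axis(seg_anc, seg_id, axis=1)
        hap_chunks.append(ancestral[anc_idx, np.arange(m)[None, :]])
    haps = np.concatenate(hap_chunks, axis=1)  # (n_haps, n_snps)
    haps = haps.reshape(n_founders, 2, marker_map.n_snps)
    if founder_ids is None:
        founder_ids = [f"F{i + 1}" for i in range(n_founders)]
    return PhasedHaplotypes(haps, founder_ids, marker_map.snps), marker_map


# --------------------------------------------------------------- pedigrees


def make_pedigree(design: PopulationDesign, seed: int) -> tuple[Pedigree, pd.DataFrame]:
    """Draw the mating design; returns pedigree plus a family table.

    Sires are ``S1..``, dams ``D1..``, offspring ``O1..``.  Factorial mating
    samples distinct sire x dam pairs uniformly; monogamous pairs the i-th
    sire with the i-th dam.
    """
    rng = substream(seed, "pedigree")
    sires = [f"S{i + 1}" for i in range(design.n_sires)]
    dams = [f"D{i + 1}" for i in range(design.n_dams)]
    if design.mating == "monogamous":
        pairs = list(zip(sires, dams))[: design.n_families]
    else:
        flat = rng.choice(
            design.n_sires * design.n_dams, size=design.n_families, replace=False
        )
        pairs = [(sires[k // design.n_dams], dams[k % design.n_dams]) for k in flat]
    records = [(s, "0", "0") for s in sires] + [(d, "0", "0") for d in dams]
    fam_rows = []
    count = 0
    for fam, (s, d) in enumerate(pairs, start=1):
        for _ in range(design.offspring_per_family):
            count += 1
            oid = f"O{count}"
            records.append((oid, s, d))
            fam_rows.append({"id": oid, "family": fam, "sire": s, "dam": d})
    return Pedigree.from_records(records), pd.DataFrame(fam_rows)


# --------------------------------------------------------------- gene drop


def _genetic_lengths(
    chromosomes: list[ChromosomeSpec] | None, marker_map: MarkerMap
) -> dict[str, float]:
    if chromosomes is not None:
        return {c.name: c.cM for c in chromosomes}
    # default 1 cM/Mb of mapped length
    return {c: l / 1e6 for c, l in marker_map.chrom_length_bp().items()}


def _draw_gamete(parent_hap, chrom_idx, chrom_pos, chrom_cM, chrom_len_bp, rng):
    """One recombinant gamete across all chromosomes (Haldane, no interference)."""
    n = sum(len(ix) for ix in chrom_idx)
    gamete = np.empty(n, dtype=np.int8)
    for ix, pos, cM, Lbp in zip(chrom_idx, chrom_pos, chrom_cM, chrom_len_bp):
        n_co = rng.poisson(cM / 100.0)
        start = rng.integers(0, 2)
        if n_co == 0:
            gamete[ix] = parent_hap[start, ix]
            continue
        co_bp = np.sort(rng.uniform(0.0, 1.0, size=n_co)) * Lbp
        phase = (start + np.searchsorted(co_bp, pos)) % 2
        gamete[ix] = parent_hap[phase, ix]
    return gamete


def gene_drop(
    pedigree: Pedigree,
    founder_haps: PhasedHaplotypes,
    marker_map: MarkerMap,
    seed: int,
    chromosomes: list[ChromosomeSpec] | None = None,
    genotyping_error: float = 0.0,
) -> SimOutput:
    """Drop founder haplotypes down the pedigree with recombination.

    Per chromosome and gamete the crossover count is Poisson with mean
    ``genetic_length_cM / 100`` and crossover positions are uniform on the
    genetic map (Haldane, no interference), assuming a uniform cM/bp rate.
    Output is Mendelian-consistent by construction; an optional symmetric
    per-genotype error rate perturbs the reported genotype matrix only.
    """
    if marker_map.snps != founder_haps.snps:
        raise ValueError("marker map and founder haplotypes disagree on SNPs")
    for ind, sire, dam in pedigree.table.itertuples(index=False):
        if (sire == "0") != (dam == "0"):
            raise ValueError(
                f"{ind} has exactly one known parent; two-generation designs "
                "require both or neither"
            )
    founders = pedigree.founders()
    missing = [f for f in founders if f not in founder_haps.ids]
    if missing:
        raise ValueError(f"no founder haplotypes for {missing[:3]}")

    rng = substream(seed, "gametes")
    lengths_cM = _genetic_lengths(chromosomes, marker_map)
    lengths_bp = marker_map.chrom_length_bp()
    if chromosomes is not None:
        lengths_bp = {c.name: c.length_bp for c in chromosomes}
    slices = marker_map.chrom_slices()
    chrom_names = marker_map.chromosomes()
    chrom_idx = [slices[c] for c in chrom_names]
    positions = marker_map.table["pos"].to_numpy().astype(float)
    chrom_pos = [positions[ix] for ix in chrom_idx]
    chrom_cM = [lengths_cM[c] for c in chrom_names]
    chrom_Lbp = [float(lengths_bp[c]) for c in chrom_names]

    ids = pedigree.ids
    n, m = len(ids), marker_map.n_snps
    haps = np.zeros((n, 2, m), dtype=np.int8)
    index = {s: i for i, s in enumerate(ids)}
    for ind, sire, dam in pedigree.table.itertuples(index=False):
        i = index[ind]
        if sire == "0":
            haps[i] = founder_haps.of(ind)
        else:
            for k, parent in enumerate((sire, dam)):
                haps[i, k] = _draw_gamete(
                    haps[index[parent]], chrom_idx, chrom_pos, chrom_cM, chrom_Lbp, rng
                )
    phased = PhasedHaplotypes(haps, ids, marker_map.snps)
    dosages = haps.sum(axis=1).astype(np.int8)
    if genotyping_error > 0:
        err_rng = substream(seed, "genotyping-error")
        flip = err_rng.random(dosages.shape) < genotyping_error
        shift = err_rng.integers(1, 3, size=dosages.shape)
        dosages = np.where(flip, (dosages + shift) % 3, dosages).astype(np.int8)
    geno = GenotypeMatrix(dosages, ids, marker_map.snps)
    return SimOutput(
        haplotypes=phased,
        genotypes=geno,
        pedigree=pedigree,
        marker_map=marker_map,
        chromosomes=tuple(chromosomes) if chromosomes else (),
        parent_ids=founders,
        offspring_ids=pedigree.offspring(),
        seed=seed,
    )


# -------------------------------------------------------------- phenotypes


def qtl_spacing_weights(marker_map: MarkerMap) -> np.ndarray:
    """Per-SNP weight proportional to the physical interval it represents.

    Sampling QTL with these weights makes causal positions uniform along
    the genome instead of proportional to local marker density, decoupling
    the trait architecture from the (clustered) assay design.
    """
    pos = marker_map.table["pos"].to_numpy(dtype=float)
    w = np.empty(marker_map.n_snps)
    for idx in marker_map.chrom_slices().values():
        p = pos[idx]
        if len(p) == 1:
            w[idx] = 1.0
            continue
        mid = np.empty(len(p))
        mid[1:-1] = (p[2:] - p[:-2]) / 2.0
        mid[0] = p[1] - p[0]
        mid[-1] = p[-1] - p[-2]
        w[idx] = mid
    return w / w.sum()


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    model: TraitModel,
    seed: int,
    mu: float = 0.0,
    qtl_weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Phenotypes plus true breeding values under an additive QTL model.

    QTL are drawn among segregating SNPs (optionally weighted, e.g. by
    :func:`qtl_spacing_weights` so causal loci are uniform in bp), effects
    are Normal and rescaled so the realized breeding-value variance is
    exactly ``h2_target`` of the phenotypic variance parameter (breeding
    values variance 1 by convention, residual variance ``(1 - h2) / h2``).
    Binary traits threshold the liability at its empirical
    ``1 - prevalence`` quantile.
    """
    rng_eff = substream(seed, "effects")
    rng_noise = substream(seed, "noise")
    p = genotypes.allele_freq()
    segregating = np.where((p > 0) & (p < 1))[0]
    if len(segregating) == 0:
        raise ValueError("all SNPs monomorphic; cannot place QTL")
    if model.n_qtl > len(segregating):
        raise ValueError(
            f"n_qtl={model.n_qtl} exceeds {len(segregating)} segregating SNPs"
        )
    if qtl_weights is None:
        probs = None
    else:
        qtl_weights = np.asarray(qtl_weights, dtype=float)
        if len(qtl_weights) != genotypes.n_snps:
            raise ValueError("need one QTL weight per SNP")
        probs = qtl_weights[segregating]
        probs = probs / probs.sum()
    qtl_idx = np.sort(
        rng_eff.choice(segregating, size=model.n_qtl, replace=False, p=probs)
    )
    effects = rng_eff.normal(0.0, 1.0 / np.sqrt(model.n_qtl), size=model.n_qtl)
    dos = genotypes.dosages[:, qtl_idx].astype(float)
    dos[dos < 0] = np.nan
    dos = np.where(np.isnan(dos), 2 * p[qtl_idx], dos)  # tolerate rare missing
    bv = dos @ effects
    sd_bv = bv.std()
    if sd_bv == 0:
        raise ValueError("breeding values degenerate; increase n_qtl or diversity")
    # realized var(a) = 1 exactly; var(e) chosen so h2 = var(a)/(var(a)+var(e))
    effects = effects / sd_bv
    bv = (bv - bv.mean()) / sd_bv
    var_e = (1.0 - model.h2_target) / model.h2_target
    liability = mu + bv + rng_noise.normal(0.0, np.sqrt(var_e), size=len(bv))

    pheno = pd.DataFrame({"id": genotypes.ids})
    for fe in model.fixed_effects:
        levels = rng_noise.integers(0, fe.n_levels, size=len(bv))
        level_effects = rng_noise.normal(0.0, fe.sd, size=fe.n_levels)
        pheno[fe.name] = [f"{fe.name}{l + 1}" for l in levels]
        liability = liability + level_effects[levels]
    if model.trait_type == "binary":
        threshold = np.quantile(liability, 1.0 - model.prevalence)
        pheno["trait"] = (liability > threshold).astype(int)
    else:
        pheno["trait"] = liability
    true_bv = pd.Series(bv, index=pd.Index(genotypes.ids, name="id"), name="true_bv")
    qtl = pd.DataFrame(
        {
            "snp": [genotypes.snps[j] for j in qtl_idx],
            "effect": effects,
            "freq": p[qtl_idx],
        }
    )
    return pheno, true_bv, qtl


# ----------------------------------------------------------------- presets


@dataclass(frozen=True)
class PopulationPreset:
    """A ready-to-run population recipe (chromosomes, design, LD, trait)."""

    chromosomes: tuple[ChromosomeSpec, ...]
    design: PopulationDesign
    n_ancestral: int
    switch_rate: float
    maf_law: tuple = ("uniform", 0.05, 0.5)
    trait: TraitModel = field(
        default_factory=lambda: TraitModel(h2_target=0.3, n_qtl=200)
    )


def salmon_like(
    n_snps: int = 10_000,
    n_chromosomes: int = 20,
    n_parents: int = 60,
    n_families: int = 100,
    n_offspring: int = 1_000,
    h2: float = 0.3,
    trait_type: str = "continuous",
    prevalence: float | None = None,
) -> PopulationPreset:
    """Salmonid-style preset: large chromosomes, slow LD decay, ~100 families."""
    per = n_snps // n_chromosomes
    counts = [per + (1 if i < n_snps - per * n_chromosomes else 0) for i in range(n_chromosomes)]
    chroms = tuple(
        ChromosomeSpec(f"chr{i + 1}", length_bp=50_000_000, n_snps=c, genetic_length_cM=50.0)
        for i, c in enumerate(counts)
    )
    design = PopulationDesign(
        n_sires=n_parents // 2,
        n_dams=n_parents - n_parents // 2,
        n_families=n_families,
        offspring_per_family=max(1, n_offspring // n_families),
    )
    trait = TraitModel(
        h2_target=h2,
        n_qtl=min(200, n_snps // 4),
        trait_type=trait_type,
        prevalence=prevalence,
    )
    return PopulationPreset(
        chromosomes=chroms,
        design=design,
        n_ancestral=8,
        switch_rate=2e-7,  # ~5 Mb ancestral segments: elevated LD over a
        # few Mb, near zero beyond ~15 Mb (salmonid-style long-range LD)
        trait=trait,
    )


def oyster_like(
    n_snps: int = 8_000,
    n_chromosomes: int = 10,
    n_parents: int = 44,
    n_families: int = 30,
    n_offspring: int = 720,
    h2: float = 0.6,
) -> PopulationPreset:
    """Bivalve-style preset: fewer chromosomes, rapid LD decay."""
    per = n_snps // n_chromosomes
    counts = [per + (1 if i < n_snps - per * n_chromosomes else 0) for i in range(n_chromosomes)]
    chroms = tuple(
        ChromosomeSpec(f"chr{i + 1}", length_bp=60_000_000, n_snps=c, genetic_length_cM=60.0)
        for i, c in enumerate(counts)
    )
    design = PopulationDesign(
        n_sires=n_parents // 2,
        n_dams=n_parents - n_parents // 2,
        n_families=n_families,
        offspring_per_family=max(1, n_offspring // n_families),
    )
    return PopulationPreset(
        chromosomes=chroms,
        design=design,
        n_ancestral=16,
        switch_rate=2e-6,  # ~0.5 Mb ancestral segments: rapid decay
        trait=TraitModel(h2_target=h2, n_qtl=200),
    )


def simulate_population(
    preset: PopulationPreset, seed: int, genotyping_error: float = 0.0
) -> SimOutput:
    """End-to-end simulation: founders -> pedigree -> gene drop -> phenotypes.

    Parents carry the founder haplotypes; phenotypes are recorded on
    offspring only, matching a sib-testing breeding programme.
    """
    ped, _fam = make_pedigree(preset.design, seed)
    founders = ped.founders()
    founder_haps, mmap = simulate_founders(
        list(preset.chromosomes),
        n_founders=len(founders),
        n_ancestral=preset.n_ancestral,
        switch_rate=preset.switch_rate,
        maf_law=preset.maf_law,
        seed=seed,
        founder_ids=founders,
    )
    out = gene_drop(
        ped, founder_haps, mmap, seed,
        chromosomes=list(preset.chromosomes),
        genotyping_error=genotyping_error,
    )
    offspring_geno = out.genotypes.subset(ids=out.offspring_ids)
    pheno, bv, qtl = simulate_phenotypes(
        offspring_geno, preset.trait, seed, qtl_weights=qtl_spacing_weights(mmap)
    )
    out.phenotypes = pheno
    out.true_bv = bv
    out.qtl = qtl
    return out
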