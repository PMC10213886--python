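"""Pedigree-based imputation of offspring HD genotypes from LD panels.

The reference population is the HD-genotyped parents; targets are offspring
genotyped on an LD subset.  The imputer (i) phases the parents with a
windowed haplotype-library heuristic (or accepts true phases from the
simulator), (ii) fills genotypes forced by Mendelian rules, (iii) decodes
for each offspring gamete a two-state origin path over the parent's two
haplotypes at informative LD markers (dynamic programming, mismatch cost
per disagreement, switch cost per state change), and (iv) copies parental
alleles along the decoded path.  Markers inside a crossover interval, and
chromosomes with no informative markers, are filled by sampling from the
reference allele frequency, mirroring the random-fill convention of
family-based imputation tools.  Observed genotypes are never altered.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, MarkerMap, Pedigree, PhasedHaplotypes
from .simdata import substream

log = logging.getLogger(__name__)

# provenance codes
OBSERVED, MENDELIAN, HAPLOTYPE_COPY, RANDOM_FILL, EXTERNAL = 0, 1, 2, 3, 4
PROVENANCE_TAGS = {
    OBSERVED: "observed",
    MENDELIAN: "mendelian",
    HAPLOTYPE_COPY: "haplotype-copy",
    RANDOM_FILL: "random-fill",
    EXTERNAL: "external",
}


@dataclass
class ImputedGenotypes:
    """Complete genotypes plus per-entry provenance codes."""

    genotypes: GenotypeMatrix
    provenance: np.ndarray  # int8, same shape as dosages

    def __post_init__(self):
        if self.provenance.shape != self.genotypes.dosages.shape:
            raise ValueError("provenance shape mismatch")
        if (self.genotypes.dosages == MISSING).any():
            raise ValueError("imputed genotypes must be complete")

    def tag_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.provenance, return_counts=True)
        return {PROVENANCE_TAGS[int(v)]: int(c) for v, c in zip(vals, counts)}


@dataclass
class GameteOriginPath:
    """Two-state origin path over informative markers of one gamete."""

    marker_indices: np.ndarray  # column indices into the chromosome
    states: np.ndarray  # 0 = parental haplotype 1, 1 = haplotype 2
    cost: float
    n_switches: int

    @property
    def switch_positions(self) -> list[tuple[int, int]]:
        """(left, right) marker-index pairs flanking each state change."""
        out = []
        for k in range(1, len(self.states)):
            if self.states[k] != self.states[k - 1]:
                out.append((int(self.marker_indices[k - 1]), int(self.marker_indices[k])))
        return out


# ------------------------------------------------------------ parent phasing


def _phase_chromosome(
    g: np.ndarray, haps: np.ndarray, lo: int, hi: int, win: int, max_iter: int, enum_cap: int
) -> bool:
    """Iterative overlapping-window library phasing of one chromosome (in place).

    Windows slide by a third of their width; each parent is reassigned the
    frequency-best compatible pair (strict improvement only, which damps
    oscillation) and the pair is oriented to agree with the parent's
    current assignment over the already-updated left overlap, chaining
    phase continuity along the chromosome.  Window haplotypes are encoded
    as bit integers for speed.
    """
    n = g.shape[0]
    win = min(win, 60)  # keep bit codes inside an int64 word
    step = max(1, win // 3)
    starts = list(range(lo, max(hi - step, lo + 1), step))
    windows = [(s, min(s + win, hi)) for s in starts if min(s + win, hi) - s >= 2]
    converged = False
    for _ in range(max_iter):
        changed = False
        for a0, b0 in windows:
            m = b0 - a0
            pw = 1 << np.arange(m, dtype=np.int64)
            gw = g[:, a0:b0]
            codes = (haps[:, :, a0:b0].astype(np.int64) @ pw).tolist()  # n x 2 ints
            counts: Counter = Counter()
            for c0, c1 in codes:
                counts[c0] += 1
                counts[c1] += 1
            overlap_mask = (1 << max(1, min(win - step, m))) - 1
            het_rows = [np.where(gw[i] == 1)[0] for i in range(n)]
            # with few parents exact-match frequencies are too sparse to
            # bootstrap, so candidate haplotypes also earn credit for being
            # genotype-compatible with other parents (Clark-style parsimony)
            use_compat = n <= 24
            if use_compat:
                hom_mask = ((gw != 1).astype(np.int64) @ pw).tolist()
                hom_val = (((gw == 2).astype(np.int64)) @ pw).tolist()

            def compat(code: int, skip: int) -> int:
                return sum(
                    1
                    for j in range(n)
                    if j != skip and (code & hom_mask[j]) == hom_val[j]
                )

            for i in range(n):
                het = het_rows[i]
                if len(het) <= 1 or len(het) > enum_cap:
                    continue
                own0, own1 = codes[i]
                base = int(((gw[i] == 2).astype(np.int64) * pw).sum())
                hetbits = [int(1 << int(j)) for j in het]
                all_het = sum(hetbits)
                full = (1 << m) - 1
                own_score = (
                    (counts[own0] - 1 + 0.5 + (0.25 * compat(own0, i) if use_compat else 0))
                    * (counts[own1] - 1 + 0.5 + (0.25 * compat(own1, i) if use_compat else 0))
                )
                # candidates are ranked on (library score, oriented agreement
                # with the freshly updated left overlap, oriented full-window
                # agreement): the overlap term chains phase orientation from
                # window to window, the full term damps oscillation, and the
                # current assignment wins all ties (strict improvement only)
                best = (own_score, 2 * m, 2 * m)
                best_pair = None
                for mask in range(1 << (len(het) - 1)):
                    abits = hetbits[0]
                    for k in range(1, len(het)):
                        if (mask >> (k - 1)) & 1:
                            abits += hetbits[k]
                    ca = base + abits
                    cb = base + (all_het - abits)
                    fa = counts[ca] - (ca == own0) - (ca == own1)
                    fb = counts[cb] - (cb == own0) - (cb == own1)
                    if use_compat:
                        fa += 0.25 * compat(ca, i)
                        fb += 0.25 * compat(cb, i)
                    score = (fa + 0.5) * (fb + 0.5)
                    for x, y in ((ca, cb), (cb, ca)):
                        oa = (~(x ^ own0) & overlap_mask).bit_count() + (
                            ~(y ^ own1) & overlap_mask
                        ).bit_count()
                        fagree = (~(x ^ own0) & full).bit_count() + (
                            ~(y ^ own1) & full
                        ).bit_count()
                        if (score, oa, fagree) > best:
                            best = (score, oa, fagree)
                            best_pair = (x, y)
                if best_pair is None:
                    continue
                ca, cb = best_pair
                if (ca, cb) != (own0, own1):
                    counts[own0] -= 1
                    counts[own1] -= 1
                    counts[ca] += 1
                    counts[cb] += 1
                    codes[i] = [ca, cb]
                    haps[i, 0, a0:b0] = (ca >> np.arange(m)) & 1
                    haps[i, 1, a0:b0] = (cb >> np.arange(m)) & 1
                    changed = True
        if not changed:
            converged = True
            break
    return converged


def _repair_boundaries(g: np.ndarray, haps: np.ndarray, lo: int, hi: int, step: int, span: int = 50):
    """Repair phase orientation across homozygous runs by long-match voting.

    A stretch of homozygosity longer than the window overlap leaves the
    orientation of everything downstream locally unconstrained.  For each
    window boundary the two orientations of the right-hand tail are scored
    by the longest contiguous agreement, crossing the boundary, with any
    other parent's current haplotype; a strictly better swap is applied.
    """
    n = g.shape[0]
    for b in range(lo + step, hi, step):
        s0, s1 = max(lo, b - span), min(hi, b + span)
        left_len = b - s0
        if left_len < 1 or s1 - b < 1:
            continue
        block = haps[:, :, s0:s1].reshape(2 * n, s1 - s0)
        for i in range(n):
            if not (g[i, s0:b] == 1).any() or not (g[i, b:s1] == 1).any():
                continue  # no heterozygous anchor on one side: nothing to decide
            others = np.ones(2 * n, dtype=bool)
            others[2 * i : 2 * i + 2] = False
            cand = block[others]

            def cross(hap_left, hap_right):
                target = np.concatenate([hap_left, hap_right])
                agree = cand == target[None, :]
                lr = np.cumprod(agree[:, left_len - 1 :: -1], axis=1).sum(axis=1)
                rr = np.cumprod(agree[:, left_len:], axis=1).sum(axis=1)
                crossing = (lr > 0) & (rr > 0)
                return int((lr + rr)[crossing].max()) if crossing.any() else 0

            l0, l1 = haps[i, 0, s0:b], haps[i, 1, s0:b]
            r0, r1 = haps[i, 0, b:s1], haps[i, 1, b:s1]
            keep = cross(l0, r0) + cross(l1, r1)
            swap = cross(l0, r1) + cross(l1, r0)
            if swap > keep:
                tail = haps[i, :, b:hi].copy()
                haps[i, 0, b:hi], haps[i, 1, b:hi] = tail[1], tail[0]
                block = haps[:, :, s0:s1].reshape(2 * n, s1 - s0)
    return haps


def phase_parents(
    parent_geno: GenotypeMatrix,
    marker_map: MarkerMap,
    window_het_sites: int = 6,
    max_iter: int = 10,
    seed: int = 0,
    truth: PhasedHaplotypes | None = None,
    enum_cap: int = 12,
) -> PhasedHaplotypes:
    """Phase complete parent genotypes with a windowed haplotype library.

    Marker windows (sized so the average parent holds about
    ``window_het_sites`` heterozygous sites, sliding with two-thirds
    overlap) are phased by enumerating the compatible haplotype pairs of
    each parent and scoring them against the frequency library of all
    current assignments, orienting each update against the left overlap.
    ``truth`` switches to oracle mode and returns the simulator's phases
    for the parents.
    """
    if truth is not None:
        rows = np.array([truth._id_index[i] for i in parent_geno.ids])
        tsnp = {s: j for j, s in enumerate(truth.snps)}
        cols = np.array([tsnp[s] for s in parent_geno.snps])
        return PhasedHaplotypes(
            truth.haps[rows][:, :, cols], parent_geno.ids, parent_geno.snps
        )
    if parent_geno.missing_mask().any():
        raise ValueError("parents must be complete at HD before phasing")
    rng = substream(seed, "phase-init")
    g = parent_geno.dosages
    n, m = g.shape
    haps = np.zeros((n, 2, m), dtype=np.int8)
    hom = g != 1
    haps[:, 0, :] = np.where(hom, g // 2, 0)
    haps[:, 1, :] = haps[:, 0, :]
    het = ~hom
    rand = (rng.random((n, m)) < 0.5).astype(np.int8)
    haps[:, 0, :] = np.where(het, rand, haps[:, 0, :])
    haps[:, 1, :] = np.where(het, 1 - rand, haps[:, 1, :])

    het_rate = max(float(het.mean()), 0.02)
    win = max(2, int(round(window_het_sites / het_rate)))
    converged = True
    cols = parent_geno.snp_indices(marker_map.snps)
    if not np.array_equal(cols, np.arange(m)):
        raise ValueError("marker map must match genotype SNP order")
    for idx in marker_map.chrom_slices().values():
        lo0, hi0 = int(idx[0]), int(idx[-1]) + 1
        sub_conv = _phase_chromosome(g, haps, lo0, hi0, win, max_iter, enum_cap)
        converged = converged and sub_conv
        _repair_boundaries(g, haps, lo0, hi0, max(1, win // 3))
    if not converged:
        warnings.warn("phasing did not fully converge within max_iter; returning best")
    out = PhasedHaplotypes(haps, parent_geno.ids, parent_geno.snps)
    bad = out.to_genotypes().dosages != g
    if bad.any():  # pragma: no cover - construction guarantees consistency
        raise AssertionError("phased haplotypes inconsistent with genotypes")
    return out


# ------------------------------------------------------------ Mendelian fill


def mendelian_fill(
    offspring_ld: np.ndarray, sire_geno: np.ndarray, dam_geno: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill offspring genotypes forced by the parent pair.

    Only hom x hom parent pairs force the offspring genotype (0x0 -> 0,
    2x2 -> 2, 0x2 -> 1); everything else stays missing.  Returns the filled
    vector and a boolean mask of newly filled entries.
    """
    out = offspring_ld.copy()
    missing = out == MISSING
    forced = (sire_geno != 1) & (dam_geno != 1) & (sire_geno != MISSING) & (dam_geno != MISSING)
    fill = missing & forced
    out[fill] = (sire_geno[fill] // 2 + dam_geno[fill] // 2).astype(out.dtype)
    return out, fill


# ----------------------------------------------------- gamete origin decoding


def infer_gamete_origin(
    transmitted: np.ndarray,
    parent_hap_alleles: np.ndarray,
    marker_indices: np.ndarray,
    switch_penalty: float,
    mismatch_penalty: float,
) -> GameteOriginPath:
    """Minimal-cost two-state path over informative markers.

    ``transmitted`` holds the allele the focal parent must have transmitted
    at each informative marker; ``parent_hap_alleles`` is (2, m) with the
    parent's two haplotype alleles there.  Cost = mismatch_penalty per
    disagreement + switch_penalty per state change, minimised by dynamic
    programming; ties prefer fewer switches, then haplotype 1.
    """
    if switch_penalty <= 0 or mismatch_penalty <= 0:
        raise ValueError("penalties must be positive")
    m = len(transmitted)
    if m == 0:
        return GameteOriginPath(np.array([], dtype=int), np.array([], dtype=int), 0.0, 0)
    mism = (parent_hap_alleles != transmitted[None, :]).astype(float) * mismatch_penalty
    # dp over (cost, switches); predecessor preference: stay, then state 0
    cost = mism[:, 0].copy()
    switches = np.zeros(2, dtype=int)
    back = np.zeros((m, 2), dtype=np.int8)
    for j in range(1, m):
        new_cost = np.empty(2)
        new_sw = np.empty(2, dtype=int)
        for s in (0, 1):
            stay = (cost[s], switches[s])
            move = (cost[1 - s] + switch_penalty, switches[1 - s] + 1)
            if move < stay:
                prev = 1 - s
            elif stay < move:
                prev = s
            else:
                prev = min(s, 1 - s)  # exact tie: prefer haplotype 1 (index 0)
            new_cost[s] = (move if prev != s else stay)[0] + mism[s, j]
            new_sw[s] = (move if prev != s else stay)[1]
            back[j, s] = prev
        cost, switches = new_cost, new_sw
    end = 0 if (cost[0], switches[0], 0) <= (cost[1], switches[1], 1) else 1
    states = np.empty(m, dtype=np.int8)
    states[-1] = end
    for j in range(m - 1, 0, -1):
        states[j - 1] = back[j, states[j]]
    return GameteOriginPath(
        np.asarray(marker_indices, dtype=int),
        states,
        float(cost[end]),
        int(np.count_nonzero(np.diff(states))),
    )


def informative_markers(
    offspring_geno: np.ndarray, other_parent_geno: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Markers where the focal parent's transmitted allele is determined.

    Homozygous offspring determine both transmissions; a heterozygous
    offspring determines the focal transmission only when the *other* parent
    is homozygous.  Returns (marker indices, transmitted alleles).
    """
    g = offspring_geno
    other = other_parent_geno
    obs = g != MISSING
    hom = obs & (g != 1)
    het_informative = obs & (g == 1) & (other != 1) & (other != MISSING)
    idx = np.where(hom | het_informative)[0]
    trans = np.empty(len(idx), dtype=np.int8)
    for k, j in enumerate(idx):
        if g[j] != 1:
            trans[k] = g[j] // 2
        else:
            trans[k] = 1 - other[j] // 2
    return idx, trans


# ----------------------------------------------- offspring phase refinement


def refine_parent_phase(
    parent_haps: PhasedHaplotypes,
    masked: GenotypeMatrix,
    marker_map: MarkerMap,
    ped: Pedigree,
    min_gametes: int = 4,
    flip_threshold: float = 0.5,
    max_flips_per_chrom: int = 20,
) -> PhasedHaplotypes:
    """Correct parent phase-switch errors using offspring transmissions.

    At a parent-heterozygous informative marker the transmitted allele
    identifies which parental haplotype the gamete carries, with no
    decoding.  A phase-switch error in the parent makes *every* gamete
    appear to recombine in the same marker interval, whereas a true
    crossover affects a single gamete; intervals where more than
    ``flip_threshold`` of the spanning gametes flip state (with at least
    ``min_gametes`` observations) are treated as phase errors and the
    parent's haplotypes are swapped from the interval's right edge onward.
    """
    haps = parent_haps.haps.copy()
    par_index = {s: i for i, s in enumerate(parent_haps.ids)}
    kids: dict[str, list[tuple[int, str]]] = {p: [] for p in parent_haps.ids}
    row_of = {s: i for i, s in enumerate(masked.ids)}
    for child, sire, dam in ped.trios():
        if sire in par_index and dam in par_index and child in row_of:
            kids[sire].append((row_of[child], dam))
            kids[dam].append((row_of[child], sire))
    slices = marker_map.chrom_slices()
    for parent, gametes in kids.items():
        if len(gametes) < min_gametes:
            continue
        pi = par_index[parent]
        for idx in slices.values():
            obs = []  # (informative marker local indices, transmitted alleles)
            for child_row, other in gametes:
                other_g = haps[par_index[other]][:, idx].sum(axis=0)
                inf_idx, trans = informative_markers(masked.dosages[child_row][idx], other_g)
                if len(inf_idx):
                    obs.append((inf_idx, trans))
            for _ in range(max_flips_per_chrom):
                h = haps[pi][:, idx]
                het = h[0] != h[1]
                grid: set[int] = set()
                pairs = []  # (left, right, flipped)
                for inf_idx, trans in obs:
                    sel = het[inf_idx]
                    mk, tr = inf_idx[sel], trans[sel]
                    if len(mk) < 2:
                        continue
                    states = (tr == h[1, mk]).astype(np.int8)
                    grid.update(mk.tolist())
                    for a, b, sa, sb in zip(mk[:-1], mk[1:], states[:-1], states[1:]):
                        pairs.append((int(a), int(b), sa != sb))
                if not grid or not pairs:
                    break
                grid_sorted = sorted(grid)
                best = None  # (flip_frac, total, right_edge)
                for u, v in zip(grid_sorted[:-1], grid_sorted[1:]):
                    flips = total = 0
                    for a, b, fl in pairs:
                        if a <= u and v <= b:
                            total += 1
                            flips += fl
                    if total >= min_gametes:
                        frac = flips / total
                        if frac > flip_threshold and (
                            best is None or (frac, total) > (best[0], best[1])
                        ):
                            best = (frac, total, v)
                if best is None:
                    break
                v = best[2]
                tail = idx[v:]
                swap = haps[pi, 0, tail].copy()
                haps[pi, 0, tail] = haps[pi, 1, tail]
                haps[pi, 1, tail] = swap
    return PhasedHaplotypes(haps, parent_haps.ids, parent_haps.snps)


# ------------------------------------------------------------ full imputer


def _default_switch_penalty(n_informative: int, chrom_cM: float) -> float:
    """ln(expected informative markers per crossover), floored at 0.5."""
    expected_co = max(chrom_cM / 100.0, 1e-3)
    return max(0.5, float(np.log(max(n_informative / expected_co, 2.0))))


def _copy_gamete(
    path: GameteOriginPath, parent_haps_chrom: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gamete alleles along a decoded path; returns (alleles, known mask).

    Parent-homozygous sites are forced whichever haplotype was transmitted,
    so they are copied whenever a path exists at all.  Heterozygous sites
    are copied from the path state; the flanking states extend to the
    chromosome ends, and sites strictly inside a switch interval stay
    unknown (random-filled by the caller).
    """
    alleles = np.zeros(m, dtype=np.int8)
    known = np.zeros(m, dtype=bool)
    idx, states = path.marker_indices, path.states
    if len(idx) == 0:
        return alleles, known
    hom = parent_haps_chrom[0] == parent_haps_chrom[1]
    alleles[hom] = parent_haps_chrom[0][hom]
    known[hom] = True

    def fill(lo: int, hi: int, s: int) -> None:
        if hi > lo:
            sel = ~hom[lo:hi]
            alleles[lo:hi][sel] = parent_haps_chrom[s, lo:hi][sel]
            known[lo:hi][sel] = True

    fill(0, int(idx[0]) + 1, states[0])
    for k in range(1, len(idx)):
        a, b = int(idx[k - 1]), int(idx[k])
        if states[k] == states[k - 1]:
            fill(a + 1, b + 1, states[k])
        else:  # crossover somewhere in (a, b): leave the interval unknown
            fill(b, b + 1, states[k])
    fill(int(idx[-1]) + 1, m, states[-1])
    return alleles, known


@dataclass
class ReferenceImputer:
    """Two-generation haplotype-copy imputer with random-fill fallback."""

    mismatch_penalty: float = 1.0
    switch_penalty: float | None = None  # None -> per-chromosome heuristic
    genetic_lengths: dict[str, float] | None = None  # cM; default 1 cM/Mb
    refine_phase: bool = True  # offspring-transmission phase correction


def impute_offspring(
    masked: GenotypeMatrix,
    marker_map: MarkerMap,
    ped: Pedigree,
    parent_haps: PhasedHaplotypes,
    seed: int = 0,
    options: ReferenceImputer | None = None,
) -> ImputedGenotypes:
    """Impute every individual with missing genotypes from its parents.

    Parents (and any complete individual) pass through as observed.  For
    each offspring gamete a two-state origin path is decoded per chromosome
    at the informative LD markers and parental alleles are copied along it;
    switch intervals and uninformative chromosomes fall back to sampling
    each allele copy independently from the reference allele frequency.
    """
    opts = options or ReferenceImputer()
    rng = substream(seed, "random-fill")
    if marker_map.snps != masked.snps:
        raise ValueError("marker map and genotype SNP order differ")
    parents_set = set(parent_haps.ids)
    ref_geno = masked.subset(ids=[i for i in masked.ids if i in parents_set])
    if ref_geno.missing_mask().any():
        raise ValueError("reference (parent) genotypes must be complete")
    p_ref = ref_geno.allele_freq()
    if opts.refine_phase:
        parent_haps = refine_parent_phase(parent_haps, masked, marker_map, ped)

    out = masked.dosages.copy()
    prov = np.full(out.shape, OBSERVED, dtype=np.int8)
    slices = marker_map.chrom_slices()
    chrom_names = marker_map.chromosomes()
    lengths = opts.genetic_lengths or {
        c: l / 1e6 for c, l in marker_map.chrom_length_bp().items()
    }
    par_index = {s: i for i, s in enumerate(parent_haps.ids)}

    ped_parents = {r[0]: (r[1], r[2]) for r in ped.table.itertuples(index=False)}
    for i, ind in enumerate(masked.ids):
        row0 = masked.dosages[i]  # pristine observations for informativeness
        miss0 = row0 == MISSING
        if not miss0.any():
            continue
        sire, dam = ped_parents.get(ind, ("0", "0"))
        if sire in par_index and dam in par_index:
            sire_g = parent_haps.haps[par_index[sire]].sum(axis=0)
            dam_g = parent_haps.haps[par_index[dam]].sum(axis=0)
            filled, fmask = mendelian_fill(row0, sire_g, dam_g)
            out[i] = filled
            prov[i][fmask] = MENDELIAN
            gam = np.zeros((2, masked.n_snps), dtype=np.int8)
            gam_known = np.zeros((2, masked.n_snps), dtype=bool)
            for c in chrom_names:
                idx = slices[c]
                g_off = row0[idx]
                for k, (par, other_g) in enumerate(
                    ((sire, dam_g[idx]), (dam, sire_g[idx]))
                ):
                    haps_c = parent_haps.haps[par_index[par]][:, idx]
                    inf_idx, trans = informative_markers(g_off, other_g)
                    # only parent-het sites distinguish the two states
                    het = haps_c[0, inf_idx] != haps_c[1, inf_idx]
                    inf_idx, trans = inf_idx[het], trans[het]
                    if len(inf_idx) == 0:
                        continue
                    sw = opts.switch_penalty
                    if sw is None:
                        sw = _default_switch_penalty(len(inf_idx), lengths[c])
                    path = infer_gamete_origin(
                        trans, haps_c[:, inf_idx], inf_idx, sw, opts.mismatch_penalty
                    )
                    alleles, known = _copy_gamete(path, haps_c, len(idx))
                    gam[k, idx] = alleles
                    gam_known[k, idx] = known
            both = gam_known[0] & gam_known[1]
            copy_sites = miss0 & (prov[i] != MENDELIAN) & both
            out[i][copy_sites] = gam[0][copy_sites] + gam[1][copy_sites]
            prov[i][copy_sites] = HAPLOTYPE_COPY
            # one known gamete + one random allele, or fully random
            rest = miss0 & (out[i] == MISSING)
            if rest.any():
                j = np.where(rest)[0]
                a1 = np.where(
                    gam_known[0, j], gam[0, j], (rng.random(len(j)) < p_ref[j]).astype(np.int8)
                )
                a2 = np.where(
                    gam_known[1, j], gam[1, j], (rng.random(len(j)) < p_ref[j]).astype(np.int8)
                )
                out[i][j] = a1 + a2
                prov[i][j] = RANDOM_FILL
        else:
            j = np.where(miss0)[0]
            draws = (rng.random((len(j), 2)) < p_ref[j][:, None]).sum(axis=1)
            out[i][j] = draws.astype(np.int8)
            prov[i][j] = RANDOM_FILL
    return ImputedGenotypes(GenotypeMatrix(out, masked.ids, masked.snps), prov)


def impute_reference(
    masked: GenotypeMatrix,
    marker_map: MarkerMap,
    ped: Pedigree,
    seed: int = 0,
    truth_haps: PhasedHaplotypes | None = None,
    options: ReferenceImputer | None = None,
    window_het_sites: int = 6,
) -> ImputedGenotypes:
    """Phase the parents then impute all offspring (the default pipeline path)."""
    parents = [i for i in ped.founders() if i in set(masked.ids)]
    parent_geno = masked.subset(ids=parents)
    haps = phase_parents(
        parent_geno,
        marker_map,
        window_het_sites=window_het_sites,
        seed=seed,
        truth=truth_haps,
    )
    return impute_offspring(masked, marker_map, ped, haps, seed=seed, options=options)


# --------------------------------------------------------- external adapter


class ImputerUnavailable(RuntimeError):
    """Raised when the configured external imputation tool is absent."""


@dataclass
class ToolSpec:
    """Declaration of an external imputer's command and file dialect."""

    name: str
    command: list[str] = field(default_factory=list)  # {in} and {out} placeholders
    dialect: str = "pedmap"  # input/output file dialect


def external_imputer_adapter(
    masked: GenotypeMatrix,
    marker_map: MarkerMap,
    ped: Pedigree,
    tool: ToolSpec,
    workdir,
) -> ImputedGenotypes:
    """Round-trip genotypes through an external imputation tool.

    Writes the masked genotypes in the declared dialect, runs the tool, and
    validates that the output is complete and congruent (same individuals
    and SNPs).  External tools are not bundled; a missing executable raises
    :class:`ImputerUnavailable` so callers can skip with a message.
    """
    from pathlib import Path

    from . import io as aio

    if not tool.command:
        raise ImputerUnavailable(f"no command configured for tool {tool.name!r}")
    exe = tool.command[0]
    if shutil.which(exe) is None and not Path(exe).exists():
        raise ImputerUnavailable(f"external imputer {tool.name!r} not found ({exe})")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if tool.dialect == "pedmap":
        in_path = workdir / "input"
        out_path = workdir / "output"
        aio.write_ped_map(in_path, masked, marker_map, ped)
        cmd = [c.format(**{"in": str(in_path), "out": str(out_path)}) for c in tool.command]
        subprocess.run(cmd, check=True)
        geno, out_map = aio.read_ped_map(out_path)
    elif tool.dialect == "vcf":
        in_path = workdir / "input.vcf"
        out_path = workdir / "output.vcf"
        aio.write_vcf(in_path, masked, marker_map)
        cmd = [c.format(**{"in": str(in_path), "out": str(out_path)}) for c in tool.command]
        subprocess.run(cmd, check=True)
        geno, out_map, _ = aio.read_vcf(out_path)
    else:
        raise ValueError(f"unknown dialect {tool.dialect!r}")
    if geno.snps != masked.snps or geno.ids != masked.ids:
        raise ValueError(f"tool {tool.name!r} output has wrong individuals or SNPs")
    if geno.missing_mask().any():
        raise ValueError(f"tool {tool.name!r} left missing genotypes (incomplete output)")
    changed = masked.dosages != MISSING
    if (geno.dosages[changed] != masked.dosages[changed]).any():
        raise ValueError(f"tool {tool.name!r} altered observed genotypes")
    prov = np.where(changed, OBSERVED, EXTERNAL).astype(np.int8)
    return ImputedGenotypes(geno, prov)
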