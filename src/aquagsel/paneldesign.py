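"""Low-density panel design from a high-density marker map.

Three selection methods: evenly spaced by physical position (chromosome
allocation proportional to length, first and last SNP always kept), LD-based
(windowed greedy r-squared pruning with a threshold bisected to hit the
target density), and uniform random.  Panels are applied by masking
off-panel genotypes of the target individuals to missing; reference
(parent) genotypes are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


@dataclass
class Panel:
    """An ordered subset of the HD map."""

    snp_ids: list[str]
    method: str
    target_density: int
    adjustment: str = ""
    r2_threshold: float | None = None
    per_chromosome: dict[str, int] = field(default_factory=dict)

    @property
    def achieved_density(self) -> int:
        return len(self.snp_ids)


def _finalize(snp_ids, marker_map: MarkerMap, method, target, **kw) -> Panel:
    keep = set(snp_ids)
    table = marker_map.table
    ordered = [s for s in marker_map.snps if s in keep]
    if len(ordered) != len(keep):
        raise ValueError("panel contains SNPs outside the map")
    per_chrom = (
        table[table["snp"].isin(keep)].groupby("chrom", sort=False)["snp"].count().to_dict()
    )
    return Panel(ordered, method, int(target), per_chromosome=per_chrom, **kw)


# ------------------------------------------------------------ allocation


def allocate_per_chromosome(marker_map: MarkerMap, target: int) -> dict[str, int]:
    """Largest-remainder split of the target proportional to chromosome length.

    Length is the bp position of the last mapped SNP.  Every chromosome is
    guaranteed at least 2 (the first/last rule needs both ends); the deficit
    is taken from the largest allocations.
    """
    lengths = marker_map.chrom_length_bp()
    chroms = marker_map.chromosomes()
    if target < 2 * len(chroms):
        raise ValueError(
            f"target {target} below 2 x {len(chroms)} chromosomes (first+last rule)"
        )
    total = sum(lengths.values())
    quota = {c: target * lengths[c] / total for c in chroms}
    counts = {c: int(np.floor(quota[c])) for c in chroms}
    shortfall = target - sum(counts.values())
    # distribute by largest fractional remainder, ties broken by map order
    order = sorted(chroms, key=lambda c: (-(quota[c] - counts[c]), chroms.index(c)))
    for c in order[:shortfall]:
        counts[c] += 1
    # enforce the >= 2 floor, taking from the currently largest counts
    while any(v < 2 for v in counts.values()):
        needy = next(c for c in chroms if counts[c] < 2)
        donor = max(chroms, key=lambda c: (counts[c], -chroms.index(c)))
        if counts[donor] <= 2:
            raise ValueError("cannot allocate >= 2 SNPs to every chromosome")
        counts[donor] -= 1
        counts[needy] += 1
    return counts


# --------------------------------------------------------------- physical


def _select_evenly(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices of k SNPs: both ends plus nearest-to-equally-spaced targets.

    Equidistant ties take the higher-bp SNP; if the nearest SNP was already
    selected the next nearest unselected one is taken.
    """
    m = len(positions)
    if k >= m:
        return np.arange(m)
    chosen = {0, m - 1}
    p0, pL = positions[0], positions[-1]
    targets = p0 + (pL - p0) * np.arange(1, k - 1) / (k - 1)
    for t in targets:
        dist = np.abs(positions.astype(float) - t)
        # higher bp wins ties -> sort by (distance, -position)
        order = np.lexsort((-positions, dist))
        for idx in order:
            if idx not in chosen:
                chosen.add(int(idx))
                break
    return np.array(sorted(chosen))


def select_physical(marker_map: MarkerMap, target: int) -> Panel:
    """Evenly spaced panel by physical position, first+last always included.

    A chromosome with fewer SNPs than its allocation contributes all of them
    and the shortfall is not redistributed, so the achieved density may fall
    slightly below the target.
    """
    counts = allocate_per_chromosome(marker_map, target)
    slices = marker_map.chrom_slices()
    positions = marker_map.table["pos"].to_numpy()
    snps = marker_map.table["snp"].to_numpy()
    selected = []
    for chrom, k in counts.items():
        idx = slices[chrom]
        if len(idx) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 SNPs")
        local = _select_evenly(positions[idx], k)
        selected.extend(snps[idx[local]])
    return _finalize(selected, marker_map, "physical", target)


# --------------------------------------------------------------- LD-based


def compute_r2(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete individuals; degenerate input (fewer than two
    complete pairs, or zero variance) returns 0 so it never drives pruning.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """r^2 matrix for a (individuals x SNPs) dosage block with missing = -1."""
    m = block.shape[1]
    out = np.zeros((m, m))
    if not (block == MISSING).any():
        x = block.astype(float)
        sd = x.std(axis=0)
        good = sd > 0
        if good.sum() >= 2:
            c = np.corrcoef(x[:, good], rowvar=False)
            sub = np.square(c)
            out[np.ix_(good, good)] = np.nan_to_num(sub)
        np.fill_diagonal(out, 1.0)
        return out
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = compute_r2(block[:, i], block[:, j])
    np.fill_diagonal(out, 1.0)
    return out


def prune_ld(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    window_ct: int,
    step_ct: int,
    r2_max: float,
) -> list[str]:
    """Windowed greedy LD pruning, PLINK ``--indep-pairwise`` style.

    Within each window of ``window_ct`` SNPs (never spanning a chromosome
    boundary), while any kept pair has r^2 strictly above the threshold, the
    highest-r^2 offending pair is found and its lower-MAF member removed
    (ties: the later SNP in map order); the window then shifts by
    ``step_ct``.  Returns kept SNP ids in map order.
    """
    if window_ct < 2:
        raise ValueError("window_ct must be >= 2")
    if step_ct <= 0:
        raise ValueError("step_ct must be positive")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0,1]")
    cols = geno.snp_indices(marker_map.snps)
    maf = geno.maf()
    removed: set[int] = set()
    slices = marker_map.chrom_slices()
    for chrom in marker_map.chromosomes():
        idx = slices[chrom]  # map-row indices on this chromosome
        start = 0
        while True:
            window = idx[start : start + window_ct]
            if len(window) >= 2:
                live = [w for w in window if w not in removed]
                gcols = cols[live]
                r2 = _pairwise_r2(geno.dosages[:, gcols])
                while True:
                    tri = np.triu(r2, 1)
                    worst = tri > r2_max
                    if not worst.any():
                        break
                    # highest-r2 pair; ties -> earliest pair in map order
                    flat = np.argmax(np.where(worst, tri, -1.0))
                    i, j = np.unravel_index(flat, tri.shape)
                    mi, mj = maf[gcols[i]], maf[gcols[j]]
                    drop = j if (mj < mi or (mj == mi)) else i
                    removed.add(live[drop])
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window_ct >= len(idx):
                break
            start += step_ct
    return [
        marker_map.table["snp"][i]
        for i in range(marker_map.n_snps)
        if i not in removed
    ]


def select_genetic(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    target: int,
    window_ct: int = 50,
    step_ct: int = 5,
    max_iter: int = 25,
) -> Panel:
    """LD-pruned panel sized by bisection over the r^2 threshold.

    The threshold is bisected until the pruned-set size is as close to the
    target as achievable; exact density is then enforced by trimming evenly
    spaced surplus SNPs or topping up with the highest-MAF excluded SNPs.
    """
    if target > marker_map.n_snps:
        raise ValueError("target exceeds HD SNP count")
    lo, hi = 0.0, 1.0
    best = None  # (gap, threshold, kept)
    kept_hi = prune_ld(geno, marker_map, window_ct, step_ct, 1.0)
    best = (abs(len(kept_hi) - target), 1.0, kept_hi)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if mid <= 0:
            break
        kept = prune_ld(geno, marker_map, window_ct, step_ct, mid)
        gap = abs(len(kept) - target)
        if gap < best[0] or (gap == best[0] and mid < best[1]):
            best = (gap, mid, kept)
        if len(kept) > target:
            hi = mid
        elif len(kept) < target:
            lo = mid
        else:
            break
    _, threshold, kept = best
    adjustment = ""
    if len(kept) > target:
        surplus = len(kept) - target
        drop_idx = set(
            np.round(np.linspace(0, len(kept) - 1, surplus)).astype(int).tolist()
        )
        # evenly indexed surplus removal; linspace may collide on tiny panels
        while len(drop_idx) < surplus:
            for i in range(len(kept)):
                if i not in drop_idx:
                    drop_idx.add(i)
                    if len(drop_idx) == surplus:
                        break
        kept = [s for i, s in enumerate(kept) if i not in drop_idx]
        adjustment = f"trimmed {surplus}"
    elif len(kept) < target:
        deficit = target - len(kept)
        maf = geno.maf()
        kept_set = set(kept)
        excluded = [
            (maf[geno.snp_indices([s])[0]], s)
            for s in marker_map.snps
            if s not in kept_set
        ]
        excluded.sort(key=lambda t: -t[0])
        kept = kept + [s for _, s in excluded[:deficit]]
        adjustment = f"topped up {deficit}"
    if adjustment:
        log.info("select_genetic density adjustment: %s (threshold %.4g)", adjustment, threshold)
    return _finalize(
        kept, marker_map, "genetic", target, adjustment=adjustment, r2_threshold=threshold
    )


# ----------------------------------------------------------------- random


def select_random(marker_map: MarkerMap, target: int, seed: int) -> Panel:
    """Uniform sample without replacement over the whole map."""
    if target > marker_map.n_snps:
        raise ValueError("target exceeds SNP count")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(marker_map.n_snps, size=target, replace=False))
    snps = [marker_map.snps[i] for i in idx]
    return _finalize(snps, marker_map, "random", target)


# ---------------------------------------------------------------- masking


def mask_to_panel(
    geno: GenotypeMatrix, panel: Panel, targets: list[str]
) -> GenotypeMatrix:
    """Set off-panel genotypes of the target individuals to missing."""
    rows = geno.id_indices(targets)
    panel_cols = set(geno.snp_indices(panel.snp_ids).tolist())
    off = np.array([j for j in range(geno.n_snps) if j not in panel_cols], dtype=int)
    masked = geno.copy()
    if len(off):
        masked.dosages[np.ix_(rows, off)] = MISSING
    return masked
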