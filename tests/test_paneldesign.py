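"""Panel design: proportional allocation, even spacing, LD pruning, masking."""

import numpy as np
import pytest

from aquagsel.core import MISSING, GenotypeMatrix, MarkerMap
from aquagsel.paneldesign import (
    allocate_per_chromosome,
    compute_r2,
    mask_to_panel,
    prune_ld,
    select_genetic,
    select_physical,
    select_random,
)


def _map(positions_by_chrom):
    snps, chroms, pos = [], [], []
    for c, ps in positions_by_chrom.items():
        for k, p in enumerate(ps):
            snps.append(f"{c}_{k}")
            chroms.append(c)
            pos.append(p)
    return MarkerMap.from_arrays(snps, chroms, pos)


class TestAllocate:
    def test_exact_proportional_split(self):
        mmap = _map({"c1": [1, 2_000_000], "c2": [1, 1_000_000]})
        assert allocate_per_chromosome(mmap, 30) == {"c1": 20, "c2": 10}

    def test_single_chromosome_gets_everything(self):
        mmap = _map({"c1": [1, 500, 900]})
        assert allocate_per_chromosome(mmap, 7) == {"c1": 7}

    def test_largest_remainder_with_map_order_ties(self):
        mmap = _map({c: [1, 1_000_000] for c in ("c1", "c2", "c3")})
        assert allocate_per_chromosome(mmap, 10) == {"c1": 4, "c2": 3, "c3": 3}

    def test_target_below_floor_rejected(self):
        mmap = _map({"c1": [1, 100], "c2": [1, 100]})
        with pytest.raises(ValueError):
            allocate_per_chromosome(mmap, 3)


class TestSelectPhysical:
    def test_allocation_two_takes_first_and_last(self):
        mmap = _map({"c1": list(range(100, 1100, 100))})
        panel = select_physical(mmap, 2)
        assert panel.snp_ids == ["c1_0", "c1_9"]

    def test_short_chromosome_shortfall_not_redistributed(self):
        mmap = _map({"c1": [1, 10, 20, 30], "c2": [k * 10 for k in range(1, 41)]})
        # c1 is ~7% of total length; force its allocation above its SNP count
        counts = allocate_per_chromosome(mmap, 40)
        panel = select_physical(mmap, 40)
        assert panel.per_chromosome["c1"] == min(4, counts["c1"])
        if counts["c1"] > 4:
            assert panel.achieved_density < 40

    def test_nearest_position_tie_goes_to_higher_bp(self):
        mmap = _map({"c1": [1, 40, 60, 100]})
        panel = select_physical(mmap, 3)
        chosen_pos = sorted(
            mmap.table.set_index("snp").loc[panel.snp_ids, "pos"].tolist()
        )
        assert chosen_pos == [1, 60, 100]

    def test_chromosome_ends_always_in_panel(self, qc_population):
        _, mmap = qc_population
        panel = select_physical(mmap, 300)
        table = mmap.table
        chosen = set(panel.snp_ids)
        for chrom, sub in table.groupby("chrom", sort=False):
            assert sub["snp"].iloc[0] in chosen
            assert sub["snp"].iloc[-1] in chosen
        assert panel.achieved_density == 300


class TestComputeR2:
    def test_identical_columns_give_one(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert compute_r2(a, a.copy()) == pytest.approx(1.0)

    def test_independent_permutation_is_near_zero(self, rng):
        a = rng.integers(0, 3, size=1000)
        b = rng.permutation(a)
        assert compute_r2(a, b) < 0.02

    def test_hand_computed_zero_case(self):
        assert compute_r2(np.array([0, 0, 2, 2]), np.array([0, 2, 0, 2])) == 0.0

    def test_zero_variance_defined_as_zero(self):
        assert compute_r2(np.ones(5), np.array([0, 1, 2, 1, 0])) == 0.0

    def test_missing_handled_pairwise_complete(self):
        a = np.array([0, 1, 2, MISSING, 2])
        b = np.array([0, 1, 2, 2, MISSING])
        assert compute_r2(a, b) == pytest.approx(1.0)


def prune_oracle(dosages, mafs, r2_max):
    """Greedy full-matrix pruning oracle: repeatedly drop the lower-MAF member
    of the highest-r2 offending pair (ties: later map order)."""
    m = dosages.shape[1]
    alive = list(range(m))
    while True:
        best = None
        for ai, i in enumerate(alive):
            for j in alive[ai + 1:]:
                r2 = compute_r2(dosages[:, i], dosages[:, j])
                if r2 > r2_max and (best is None or r2 > best[0] + 1e-15):
                    best = (r2, i, j)
        if best is None:
            return alive
        _, i, j = best
        drop = j if mafs[j] <= mafs[i] else i
        alive.remove(drop)


class TestPruneLD:
    def test_duplicated_column_prunes_exactly_one(self, rng):
        col = rng.integers(0, 3, size=40).astype(np.int8)
        d = np.column_stack([col, col, rng.integers(0, 3, size=40)]).astype(np.int8)
        geno = GenotypeMatrix(d, [f"i{k}" for k in range(40)], ["a", "b", "c"])
        mmap = _map({"c1": [10, 20, 30]})
        mmap.table["snp"] = ["a", "b", "c"]
        mmap = MarkerMap(mmap.table)
        kept = prune_ld(geno, mmap, window_ct=3, step_ct=1, r2_max=0.5)
        assert sum(s in kept for s in ("a", "b")) == 1

    def test_independent_snps_untouched(self, rng):
        d = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        snps = [f"s{k}" for k in range(10)]
        geno = GenotypeMatrix(d, [f"i{k}" for k in range(200)], snps)
        mmap = MarkerMap.from_arrays(snps, ["c1"] * 10, list(range(10, 110, 10)))
        kept = prune_ld(geno, mmap, window_ct=10, step_ct=2, r2_max=0.9)
        assert kept == snps

    def test_matches_full_matrix_greedy_oracle(self, rng):
        """Window covering the whole chromosome reduces to global greedy."""
        for _ in range(25):
            n, m = 30, int(rng.integers(5, 15))
            base = rng.integers(0, 3, size=(n, m))
            # plant correlated pairs by copying columns with noise
            for j in range(1, m, 3):
                base[:, j] = np.where(rng.random(n) < 0.9, base[:, j - 1], base[:, j])
            d = base.astype(np.int8)
            snps = [f"s{k}" for k in range(m)]
            geno = GenotypeMatrix(d, [f"i{k}" for k in range(n)], snps)
            mmap = MarkerMap.from_arrays(snps, ["c1"] * m, list(range(10, 10 * m + 10, 10)))
            kept = prune_ld(geno, mmap, window_ct=m, step_ct=1, r2_max=0.4)
            want = prune_oracle(d, geno.maf(), 0.4)
            assert kept == [snps[k] for k in want]

    def test_no_kept_pair_exceeds_threshold_within_window(self, rng):
        d = rng.integers(0, 3, size=(60, 20)).astype(np.int8)
        d[:, 1] = d[:, 0]
        d[:, 11] = np.where(rng.random(60) < 0.95, d[:, 10], d[:, 11])
        snps = [f"s{k}" for k in range(20)]
        geno = GenotypeMatrix(d, [f"i{k}" for k in range(60)], snps)
        mmap = MarkerMap.from_arrays(snps, ["c1"] * 20, list(range(10, 210, 10)))
        kept = prune_ld(geno, mmap, window_ct=8, step_ct=2, r2_max=0.5)
        cols = geno.snp_indices(kept)
        for a in range(len(cols)):
            for b in range(a + 1, min(a + 8, len(cols))):
                assert compute_r2(geno.dosages[:, cols[a]], geno.dosages[:, cols[b]]) <= 0.5 + 1e-12

    def test_parameter_validation(self, qc_population):
        geno, mmap = qc_population
        with pytest.raises(ValueError):
            prune_ld(geno, mmap, window_ct=1, step_ct=1, r2_max=0.5)
        with pytest.raises(ValueError):
            prune_ld(geno, mmap, window_ct=5, step_ct=0, r2_max=0.5)


class TestSelectGenetic:
    def test_full_target_returns_identity_panel(self, qc_population):
        geno, mmap = qc_population
        sub_snps = mmap.snps[:200]
        sub_map = mmap.subset(sub_snps)
        panel = select_genetic(geno.subset(snps=sub_snps), sub_map, 200)
        assert panel.snp_ids == sub_snps

    def test_exact_density_achieved_with_adjustment(self, qc_population):
        geno, mmap = qc_population
        chrom = mmap.chromosomes()[0]
        snps = mmap.table.loc[mmap.table["chrom"] == chrom, "snp"].tolist()
        panel = select_genetic(geno.subset(snps=snps), mmap.subset(snps), 60)
        assert panel.achieved_density == 60
        assert panel.r2_threshold is not None

    def test_pruned_size_monotone_in_threshold(self, qc_population):
        geno, mmap = qc_population
        snps = mmap.snps[:300]
        sub_map = mmap.subset(snps)
        sub = geno.subset(snps=snps)
        sizes = [
            len(prune_ld(sub, sub_map, 50, 5, t)) for t in (0.05, 0.2, 0.5, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes)


class TestSelectRandom:
    def test_full_density_is_identity(self, qc_population):
        _, mmap = qc_population
        panel = select_random(mmap, mmap.n_snps, seed=1)
        assert panel.snp_ids == mmap.snps

    def test_deterministic_given_seed(self, qc_population):
        _, mmap = qc_population
        a = select_random(mmap, 300, seed=5)
        b = select_random(mmap, 300, seed=5)
        c = select_random(mmap, 300, seed=6)
        assert a.snp_ids == b.snp_ids
        assert a.snp_ids != c.snp_ids

    def test_per_chromosome_counts_match_multinomial_expectation(self):
        mmap = _map({c: list(range(100, 100 * 101, 100)) for c in ("c1", "c2", "c3")})
        counts = np.zeros(3)
        for s in range(10_000):
            panel = select_random(mmap, 300, seed=s)
            counts += [panel.per_chromosome.get(c, 0) for c in ("c1", "c2", "c3")]
        means = counts / 10_000
        assert np.all(np.abs(means - 100) < 2)

    def test_oversized_target_rejected(self, qc_population):
        _, mmap = qc_population
        with pytest.raises(ValueError):
            select_random(mmap, mmap.n_snps + 1, seed=0)


class TestMaskToPanel:
    def test_full_panel_is_identity(self, qc_population, small_sim):
        geno, mmap = qc_population
        panel = select_random(mmap, mmap.n_snps, seed=1)
        masked = mask_to_panel(geno, panel, small_sim.offspring_ids)
        assert np.array_equal(masked.dosages, geno.dosages)

    def test_masked_count_per_target(self, qc_population, small_sim):
        geno, mmap = qc_population
        panel = select_physical(mmap, 300)
        masked = mask_to_panel(geno, panel, small_sim.offspring_ids)
        rows = masked.id_indices(small_sim.offspring_ids)
        per_ind = (masked.dosages[rows] == MISSING).sum(axis=1)
        expected = geno.n_snps - panel.achieved_density
        assert np.all(per_ind == expected)

    def test_reference_parents_untouched(self, qc_population, small_sim):
        geno, mmap = qc_population
        panel = select_physical(mmap, 300)
        masked = mask_to_panel(geno, panel, small_sim.offspring_ids)
        rows = masked.id_indices(small_sim.parent_ids)
        assert (masked.dosages[rows] != MISSING).all()

    def test_unknown_target_rejected(self, qc_population):
        geno, mmap = qc_population
        panel = select_physical(mmap, 300)
        with pytest.raises(KeyError):
            mask_to_panel(geno, panel, ["nobody"])
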