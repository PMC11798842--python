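"""Generators: landscapes, co-distributed groups, assessments, abiotic layers."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from surrosai import (
    CategoryMixSpec,
    CoDistributionSpec,
    Grid,
    LandscapeSpec,
    generate_abiotic,
    generate_assessments,
    generate_correlated_group,
    generate_occurrences,
    richness_map,
)


def four_connected(cells, n_cols):
    """True when the cell set forms one 4-connected component."""
    cells = set(int(c) for c in cells)
    seen = {next(iter(cells))}
    stack = list(seen)
    while stack:
        c = stack.pop()
        r, k = divmod(c, n_cols)
        for nb in (c - n_cols, c + n_cols, c - 1 if k > 0 else -1,
                   c + 1 if k < n_cols - 1 else -1):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == cells


class TestGenerateOccurrences:
    def test_fixed_single_cell_ranges(self):
        m = generate_occurrences(
            LandscapeSpec(10, 10, 5, range_size_distribution=("fixed", 1), seed=0)
        )
        assert np.array_equal(m.range_sizes(), np.ones(5))
        assert richness_map(m).sum() == 5

    def test_seeded_determinism(self):
        spec = LandscapeSpec(15, 15, 500, range_size_distribution=("lognormal", 2, 1), seed=7)
        a = generate_occurrences(spec)
        b = generate_occurrences(spec)
        assert (a.matrix != b.matrix).nnz == 0

    def test_mean_log_range_size_matches_monte_carlo(self):
        """Oracle: the mean log size of the post-rounding pipeline, estimated
        by direct Monte-Carlo on raw lognormal draws."""
        mu, sigma, n = 2.0, 1.0, 2000
        mc = np.random.default_rng(999)
        draws = np.clip(np.rint(mc.lognormal(mu, sigma, size=200_000)), 1, None)
        expected = np.log(draws).mean()
        se = np.log(draws).std() / np.sqrt(n)

        spec = LandscapeSpec(60, 60, n, range_size_distribution=("lognormal", mu, sigma),
                             seed=31)
        m = generate_occurrences(spec)
        observed = np.log(m.range_sizes()).mean()
        assert abs(observed - expected) < 3 * se

    def test_contiguous_ranges_are_4_connected(self):
        m = generate_occurrences(LandscapeSpec(12, 12, 40, seed=3))
        for j in range(m.n_species):
            cells = m.matrix[j].indices
            assert four_connected(cells, 12)

    def test_every_species_occupies_at_least_one_cell(self):
        m = generate_occurrences(LandscapeSpec(8, 8, 100, seed=5))
        assert m.range_sizes().min() >= 1

    def test_occupancy_conservation(self):
        m = generate_occurrences(LandscapeSpec(10, 10, 60, seed=6))
        assert richness_map(m).sum() == m.range_sizes().sum()

    def test_oversized_fixed_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds grid"):
            LandscapeSpec(3, 3, 2, range_size_distribution=("fixed", 10))


class TestGenerateCorrelatedGroup:
    def test_full_overlap_singletons_inside_base(self):
        base = generate_occurrences(LandscapeSpec(12, 12, 30, seed=1))
        targets = generate_correlated_group(
            base, CoDistributionSpec(overlap=1.0, seed=2), 40,
            range_size_distribution=("fixed", 1),
        )
        base_occ = richness_map(base) > 0
        tgt_occ = richness_map(targets) > 0
        assert np.all(base_occ[tgt_occ])

    def test_zero_overlap_richness_uncorrelated(self):
        """Permutation null: at overlap 0 the observed richness correlation
        must sit inside the null distribution of shuffled cell labels."""
        dist = ("lognormal", 1.0, 1.0)
        base = generate_occurrences(
            LandscapeSpec(30, 30, 150, range_size_distribution=dist,
                          contiguity=False, seed=8)
        )
        targets = generate_correlated_group(
            base, CoDistributionSpec(overlap=0.0, seed=9), 150,
            range_size_distribution=dist, contiguity=False,
        )
        br, tr = richness_map(base).astype(float), richness_map(targets).astype(float)
        observed = np.corrcoef(br, tr)[0, 1]
        null_rng = np.random.default_rng(10)
        null = [
            np.corrcoef(br, null_rng.permutation(tr))[0, 1] for _ in range(500)
        ]
        lo, hi = np.percentile(null, [0.5, 99.5])
        assert lo <= observed <= hi

    def test_richness_correlation_monotone_in_overlap(self):
        dist = ("lognormal", 1.0, 1.0)
        base = generate_occurrences(
            LandscapeSpec(30, 30, 150, range_size_distribution=dist, seed=11)
        )
        br = richness_map(base).astype(float)
        rs = []
        for overlap in (0.0, 0.4, 0.8):
            targets = generate_correlated_group(
                base, CoDistributionSpec(overlap=overlap, seed=12), 150,
                range_size_distribution=dist,
            )
            rs.append(np.corrcoef(br, richness_map(targets).astype(float))[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_grid_mismatch_rejected(self):
        base = generate_occurrences(LandscapeSpec(5, 5, 5, seed=1))
        layer_grid = Grid(4, 4)
        other = generate_occurrences(LandscapeSpec(4, 4, 5, seed=1))
        with pytest.raises(ValueError, match="grid"):
            generate_abiotic(layer_grid, base, correlation=0.5)
        del other


class TestGenerateAssessments:
    def test_all_mass_on_lc(self):
        props = {c: 0.0 for c in ("EX", "EW", "CR", "EN", "VU", "NT", "DD")}
        props["LC"] = 1.0
        recs = generate_assessments(50, CategoryMixSpec(proportions=props, seed=1))
        assert all(r.category == "LC" and not r.tags for r in recs)

    def test_dd_fraction_in_binomial_interval(self):
        mix = CategoryMixSpec(seed=4)
        base = mix.proportions
        props = {c: p * (1 - 0.23) / (1 - base["DD"]) for c, p in base.items() if c != "DD"}
        props["DD"] = 0.23
        recs = generate_assessments(10_000, CategoryMixSpec(proportions=props, seed=4))
        dd = sum(r.category == "DD" for r in recs)
        lo, hi = binom.ppf([0.005, 0.995], 10_000, 0.23)
        assert lo <= dd <= hi

    def test_tags_only_on_cr(self):
        mix = CategoryMixSpec(pe_rate=0.5, pew_rate=0.2, seed=3)
        recs = generate_assessments(2000, mix)
        assert all(not r.tags or r.category == "CR" for r in recs)
        assert any(r.tags for r in recs if r.category == "CR")

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CategoryMixSpec(proportions={"LC": 0.5, "DD": 0.4})


@pytest.fixture(scope="module")
def targets():
    return generate_occurrences(LandscapeSpec(50, 50, 300, seed=14))


class TestGenerateAbiotic:
    def test_perfect_correlation_orders_by_richness(self, targets):
        layer = generate_abiotic(targets.grid, targets, correlation=1.0, seed=1)
        rich = richness_map(targets)
        # monotone: higher richness never gets a lower layer value
        order = np.argsort(rich)
        assert np.all(np.diff(layer.values[order]) >= -1e-12)

    @pytest.mark.parametrize("requested", [-0.8, -0.3, 0.3, 0.8])
    def test_spearman_within_tolerance(self, targets, requested):
        layer = generate_abiotic(targets.grid, targets, correlation=requested, seed=2)
        rho = spearmanr(layer.values, richness_map(targets)).statistic
        assert abs(rho - requested) < 0.15

    def test_zero_correlation_near_zero_rho(self, targets):
        layer = generate_abiotic(targets.grid, targets, correlation=0.0, seed=6)
        rho = spearmanr(layer.values, richness_map(targets)).statistic
        assert abs(rho) < 0.1

    def test_missing_fraction_in_binomial_interval(self, targets):
        layer = generate_abiotic(targets.grid, targets, correlation=0.0,
                                 missing_fraction=0.12, seed=7)
        lo, hi = binom.ppf([0.005, 0.995], targets.grid.n_cells, 0.12)
        assert lo <= layer.missing.sum() <= hi
        assert np.all(np.isnan(layer.values[layer.missing]))

    def test_parameter_validation(self, targets):
        with pytest.raises(ValueError, match="correlation"):
            generate_abiotic(targets.grid, targets, correlation=1.5)
        with pytest.raises(ValueError, match="missing_fraction"):
            generate_abiotic(targets.grid, targets, correlation=0.0, missing_fraction=1.0)
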