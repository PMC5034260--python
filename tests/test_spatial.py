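"""Pair-correlation function, power-law fits, contact bands and clusters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdlusim
from tdlusim.fixtures import make_synthetic_pattern
from tdlusim.spatial import (
    cluster_stats,
    contact_profile,
    fit_power_law,
    radial_distribution,
)


@pytest.fixture(scope="module")
def open_domain():
    """A small all-stroma domain (no lumina) for clean pair-census checks."""
    import tdlusim.geometry as g

    comp = np.full((12, 12), g.INTERLOBULAR_STROMA, dtype=np.int8)
    comp[5:7, 5:7] = g.LUMINAL_EPITHELIUM
    comp[4:8, 4:8][np.isin(comp[4:8, 4:8], [g.INTERLOBULAR_STROMA])] = g.MYOEPITHELIUM
    return g.LatticeDomain(compartment=comp, tdlu_polygon=np.zeros((0, 2)))


def brute_force_g(points, domain, edges):
    """Independent O(n^2 + A^2) pair-census normalisation."""
    pts = np.asarray(points, float)
    adm = np.argwhere(domain.flat.reshape(domain.shape) != 0)[:, ::-1]  # (x, y)
    n, a = len(pts), len(adm)

    def pair_hist(arr):
        dists = []
        for i in range(len(arr)):
            for j in range(i + 1, len(arr)):
                dists.append(np.hypot(*(arr[i] - arr[j])))
        h, _ = np.histogram(dists, bins=edges)
        return h

    obs = pair_hist(pts)
    census = pair_hist(adm.astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = census * (n * (n - 1)) / (a * (a - 1))
        g = np.where(expected > 0, obs / expected, 0.0)
    return g[census > 0], census > 0


class TestRadialDistribution:
    def test_two_points_match_hand_census(self, open_domain):
        pts = np.array([[2, 2], [2, 5]])  # distance 3
        r, g = radial_distribution(pts, open_domain, r_max=8, bin_width=1.0)
        edges = np.arange(0.0, 9.0, 1.0)
        g_oracle, keep = brute_force_g(pts, open_domain, edges)
        assert np.allclose(g, g_oracle[: len(g)], rtol=1e-9)
        nonzero = g > 0
        assert nonzero.sum() == 1 and r[nonzero][0] == pytest.approx(3.5)

    def test_random_pattern_matches_brute_force_census(self, open_domain, rng):
        pts, _ = make_synthetic_pattern("csr", 30, seed=5, shape=open_domain.shape)
        r, g = radial_distribution(pts, open_domain, r_max=8, bin_width=1.0)
        edges = np.arange(0.0, 9.0, 1.0)
        g_oracle, _ = brute_force_g(pts, open_domain, edges)
        assert np.allclose(g, g_oracle[: len(g)], rtol=1e-9, atol=1e-12)

    def test_csr_pattern_has_unit_mean_g(self, baseline_domain):
        adm = (baseline_domain.flat != 0).reshape(baseline_domain.shape)
        means = []
        for seed in range(20):
            pts, _ = make_synthetic_pattern("csr", 500, seed=seed,
                                            shape=baseline_domain.shape, admissible=adm)
            r, g = radial_distribution(pts, baseline_domain, r_max=30)
            means.append(g[r >= 1].mean())
        assert abs(np.mean(means) - 1.0) < 0.05

    def test_tight_cluster_is_overdispersed_at_small_r(self, open_domain):
        xs, ys = np.meshgrid(np.arange(2, 5), np.arange(2, 5))
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        r, g = radial_distribution(pts, open_domain, r_max=10)
        assert g[0] > 3.0        # contact bin far above CSR
        assert g[r > 6].max() < 1.0

    def test_fewer_than_two_points_rejected(self, open_domain):
        with pytest.raises(ValueError):
            radial_distribution(np.array([[1, 1]]), open_domain)


class TestFitPowerLaw:
    def test_exact_power_law_recovered_to_machine_precision(self):
        r = np.arange(1.0, 20.0)
        fit = fit_power_law(r, 2.0 * r ** -1.5)
        assert fit.b == pytest.approx(2.0, rel=1e-12)
        assert fit.m == pytest.approx(1.5, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_unit_g_gives_trivial_fit(self):
        r = np.arange(1.0, 10.0)
        fit = fit_power_law(r, np.ones_like(r))
        assert fit.b == pytest.approx(1.0) and fit.m == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        r = np.arange(1.0, 51.0)
        ms = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = 3.0 * r ** -1.2 * np.exp(rng.normal(0, 0.1, len(r)))
            ms.append(fit_power_law(r, g).m)
        assert abs(np.mean(ms) - 1.2) < 0.1

    @settings(deadline=None, max_examples=30)
    @given(c=st.floats(0.1, 10.0))
    def test_scale_covariance(self, c):
        r = np.arange(1.0, 15.0)
        g = 1.7 * r ** -0.8
        base = fit_power_law(r, g)
        scaled = fit_power_law(r, c * g)
        assert scaled.m == pytest.approx(base.m, rel=1e-9)
        assert scaled.b == pytest.approx(c * base.b, rel=1e-9)

    def test_all_zero_g_is_an_error(self):
        with pytest.raises(ValueError):
            fit_power_law(np.arange(1.0, 5.0), np.zeros(4))


class TestContactProfile:
    def test_adjacent_cells_land_in_band_one(self, open_domain):
        d = open_domain.dist_to_epithelium
        band1 = np.argwhere(d == 1)[:, ::-1]
        prof = contact_profile(band1, open_domain)
        assert prof[1] > 0
        assert prof[0] == prof[2] == prof[3] == 0

    def test_empty_set_gives_zero_profile(self, open_domain):
        assert (contact_profile(np.empty((0, 2)), open_domain) == 0).all()

    def test_random_placement_matches_brute_tally(self, open_domain, rng):
        pts, _ = make_synthetic_pattern("csr", 40, seed=9, shape=open_domain.shape)
        prof = contact_profile(pts, open_domain)
        d = open_domain.dist_to_epithelium
        tally = np.zeros(4)
        for x, y in pts:
            tally[min(d[y, x], 3)] += 1
        assert np.allclose(prof, tally / open_domain.n_epithelial)


class TestClusterStats:
    def test_isolated_cells_form_no_clusters(self):
        pts = np.array([[0, 0], [5, 5], [10, 0], [0, 10]])
        n, sizes = cluster_stats(pts, grid_shape=(12, 12), cluster_min=3)
        assert n == 0 and sizes == []

    def test_block_of_nine_is_one_cluster(self):
        xs, ys = np.meshgrid(np.arange(3), np.arange(3))
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        n, sizes = cluster_stats(pts, grid_shape=(8, 8))
        assert n == 1 and sizes == [9]

    def _union_find_oracle(self, pts, cluster_min):
        """Independent union-find over Moore adjacency."""
        parent = {tuple(p): tuple(p) for p in pts}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        keys = set(parent)
        for x, y in keys:
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nb = (x + dx, y + dy)
                    if (dx or dy) and nb in keys:
                        parent[find((x, y))] = find(nb)
        from collections import Counter

        comp = Counter(find(k) for k in keys)
        sizes = sorted((s for s in comp.values() if s >= cluster_min), reverse=True)
        return len(sizes), sizes

    @pytest.mark.parametrize("cluster_min", [1, 3])
    def test_random_patterns_match_union_find_oracle(self, cluster_min):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_pts = rng.integers(5, 60)
            pts = np.unique(rng.integers(0, 20, size=(n_pts, 2)), axis=0)
            got = cluster_stats(pts, grid_shape=(20, 20), cluster_min=cluster_min)
            assert got == self._union_find_oracle(pts, cluster_min)
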