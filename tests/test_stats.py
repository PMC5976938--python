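"""Rank correlations, best-fit curve families and group comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

import cartiqmap as cq
from cartiqmap.stats import significance_stars


def midrank_pearson(x, y):
    """Independent oracle: Pearson correlation of midranks."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_increase_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert cq.spearman(x, np.exp(x / 5))[0] == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert cq.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([3.0, 3.0, 1.0, 5.0, 2.0, 2.0, 6.0, 4.0])
        rho, _ = cq.spearman(x, y)
        assert rho == pytest.approx(midrank_pearson(x, y), abs=1e-12)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 13)
            x = rng.integers(0, 6, n).astype(float)   # frequent ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = cq.spearman(x, y)
            assert rho == pytest.approx(midrank_pearson(x, y), abs=1e-12)

    def test_small_n_p_value_is_exact_permutation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        _, p = cq.spearman(x, y)
        # exhaustive two-sided tail over all 120 orderings
        rho_obs = midrank_pearson(x, y)
        import itertools
        count = sum(
            abs(midrank_pearson(x, np.array(perm))) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(y)
        )
        assert p == pytest.approx(count / 120, abs=1e-12)

    def test_zero_rank_variance_flagged(self):
        rho, p = cq.spearman(np.full(5, 2.0), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1, _ = cq.spearman(x, y)
        r2, _ = cq.spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)


@pytest.fixture(scope="module")
def table_inputs():
    model = cq.calibrate_default_profiles()
    spec = cq.PhantomSpec(snr=50.0, seed=4, pixel_spacing_mm=0.2)
    sample, gt = cq.make_phantom(spec, model)
    depth = cq.compute_depth(sample)
    mmaps = cq.evaluate_on_grid(depth, model)
    regions = cq.assign_regions(sample.mask, 0.2, cr_width_mm=6.0)
    rng = np.random.default_rng(4)
    qmaps = {}
    for kind, proto in [
        ("T1", cq.default_t1_protocol()),
        ("T1RHO", cq.default_t1rho_protocol()),
        ("T2STAR", cq.filter_echoes(cq.default_t2star_protocol())),
    ]:
        stack = cq.simulate_stack(gt, proto, spec, rng=rng)
        qmaps[kind] = cq.fit_map(stack, proto).relax_ms
    return qmaps, mmaps, regions


class TestCorrelationTable:
    def test_shape_is_24_rows(self, table_inputs):
        table = cq.correlation_table(*table_inputs)
        assert len(table) == 24
        assert set(table["region"]) == {"CR", "PR"}

    def test_sign_structure_mirrors_composition_links(self, table_inputs):
        """Positive links to fluid fraction imply rho>0 for FF/CFO, rho<0 for CO/PG."""
        table = cq.correlation_table(*table_inputs).set_index(["qmri", "model", "region"])
        for q in ("T1", "T1RHO", "T2STAR"):
            for region in ("CR", "PR"):
                assert table.loc[(q, "FF", region), "rho_s"] > 0
                assert table.loc[(q, "CFO", region), "rho_s"] > 0
                assert table.loc[(q, "CO", region), "rho_s"] < 0
                assert table.loc[(q, "PG", region), "rho_s"] < 0

    def test_self_pair_correlation_is_one(self, table_inputs):
        _, mmaps, regions = table_inputs
        sel = regions.region_mask("CR")
        rho, _ = cq.spearman(mmaps.ff[sel], mmaps.ff[sel])
        assert rho == pytest.approx(1.0)

    def test_stars_follow_three_tier_scheme(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == "ns"


class TestCurveFits:
    def test_exponential_self_consistency(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(0.3, 0.9, 200)
        q = 100 * np.exp(2.0 * phi) + 500
        fit = cq.fit_exponential(phi, q)
        assert fit.converged
        assert fit.a == pytest.approx(100, rel=0.01)
        assert fit.b == pytest.approx(2.0, rel=0.01)
        assert fit.c == pytest.approx(500, rel=0.01)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_flagged(self):
        fit = cq.fit_exponential(np.linspace(0, 1, 10), np.full(10, 3.0))
        assert not fit.converged

    def test_fit_never_worse_than_constant_model(self):
        rng = np.random.default_rng(3)
        phi = rng.uniform(0, 1, 100)
        q = rng.normal(size=100)
        fit = cq.fit_exponential(phi, q)
        assert fit.r2 >= 0 or not fit.converged  # constant model has R^2 = 0

    def test_sinusoidal_self_consistency(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(0, 90, 200)
        q = 50 * np.sin(np.deg2rad(theta)) + 600  # b = 1 per radian
        fit = cq.fit_sinusoidal(theta, q)
        assert fit.converged
        assert fit.a == pytest.approx(50, rel=0.01)
        assert fit.b == pytest.approx(1.0, rel=0.01)
        assert fit.c == pytest.approx(600, rel=0.01)

    def test_sinusoidal_period_aliasing_gives_equal_sse(self):
        """Shifting theta by a full period leaves the attainable SSE unchanged."""
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, 90, 100)
        q = 50 * np.sin(np.deg2rad(theta)) + 600
        f1 = cq.fit_sinusoidal(theta, q)
        f2 = cq.fit_sinusoidal(theta + 360.0, q)
        sse1 = (1 - f1.r2)
        sse2 = (1 - f2.r2)
        assert sse1 == pytest.approx(sse2, abs=1e-6)

    def test_sinusoidal_constant_response_flagged(self):
        fit = cq.fit_sinusoidal(np.linspace(0, 90, 10), np.full(10, 5.0))
        assert not fit.converged


class TestGroupComparisons:
    def test_null_rejection_rate_controlled(self):
        """Identical distributions rarely reach significance."""
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 50)
        n_sig = 0
        for _ in range(100):
            vals = rng.normal(size=100)
            comp = cq.compare_groups(vals, labels, "regions")
            n_sig += comp.p_value < 0.05
        assert n_sig <= 10

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        labels = np.repeat([0, 1], 50)
        comp = cq.compare_groups(vals, labels, "regions")
        assert comp.p_value < 0.001

    def test_posthoc_flags_only_deviant_zone(self):
        """When only the deep zone differs, Dunn flags its two pairings."""
        rng = np.random.default_rng(8)
        vals = np.concatenate([
            rng.normal(0, 1, 60), rng.normal(0, 1, 60), rng.normal(4, 1, 60)
        ])
        labels = np.repeat([0, 1, 2], 60)
        comp = cq.compare_groups(vals, labels, "zones")
        assert comp.p_value < 0.05
        ph = comp.posthoc.set_index(["group_1", "group_2"])
        assert ph.loc[("SZ", "DZ"), "significant"]
        assert ph.loc[("TZ", "DZ"), "significant"]
        assert not ph.loc[("SZ", "TZ"), "significant"]

    def test_posthoc_absent_when_omnibus_not_significant(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=90)
        labels = np.repeat([0, 1, 2], 30)
        comp = cq.compare_groups(vals, labels, "zones")
        if comp.p_value >= 0.05:
            assert comp.posthoc is None


class TestZonalSummary:
    def _labels(self):
        mask = np.ones((6, 10), bool)
        z = np.tile(np.linspace(0.01, 0.99, 6)[:, None], (1, 10))
        zones = cq.assign_zones(cq.DepthField(z=z, mask=mask))
        regions = cq.assign_regions(mask, 1.0, cr_width_mm=4.0)
        return mask, zones, regions

    def test_constant_map_summary(self):
        mask, zones, regions = self._labels()
        table = cq.zonal_summary(np.full((6, 10), 7.0), zones, regions)
        assert np.allclose(table["mean"], 7.0)
        assert np.allclose(table["sd"], 0.0)

    def test_counts_sum_to_mask_size(self):
        mask, zones, regions = self._labels()
        table = cq.zonal_summary(np.ones((6, 10)), zones, regions)
        assert table["n_pixels"].sum() == mask.sum()

    def test_modelled_cfo_transitional_mean(self, default_model):
        mask = np.ones((1, 10_000), bool)
        z = ((np.arange(10_000) + 0.5) / 10_000)[None, :]
        depth = cq.DepthField(z=z, mask=mask)
        maps = cq.evaluate_on_grid(depth, default_model)
        zones = cq.assign_zones(depth)
        with pytest.warns(UserWarning):
            regions = cq.assign_regions(mask, 1.0, cr_width_mm=10_000.0)
        table = cq.zonal_summary(maps.cfo_deg, zones, regions).set_index(["zone", "region"])
        assert table.loc[("TZ", "CR"), "mean"] == pytest.approx(45.0, abs=0.5)
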