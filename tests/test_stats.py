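import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

import rizmap as rz
from rizmap.errors import InvalidConfigurationError

from test_scoring import make_adata


def panel_small():
    return rz.ZonePanel({"A": ("a1", "a2"), "B": ("b1", "b2"), "C": ("c1", "c2")})


class TestMarkerCorrelation:
    def test_self_correlation_unit_diagonal(self):
        rng = np.random.default_rng(0)
        a = rz.normalize(make_adata(rng.poisson(5, (30, 6)),
                                    genes=["a1", "a2", "b1", "b2", "c1", "c2"]))
        rep = rz.marker_correlation(a, panel_small())
        assert np.allclose(np.diag(rep.matrix.to_numpy()), 1.0)
        assert np.allclose(rep.matrix.to_numpy(), rep.matrix.to_numpy().T)

    def test_rank_reverse_gene_is_minus_one(self):
        counts = np.zeros((10, 6), dtype=int)
        counts[:, 0] = np.arange(1, 11)
        counts[:, 2] = np.arange(10, 0, -1)
        counts[:, [1, 3, 4, 5]] = 5
        a = rz.normalize(make_adata(counts, genes=["a1", "a2", "b1", "b2", "c1", "c2"]))
        rep = rz.marker_correlation(a, panel_small())
        assert rep.matrix.loc["a1", "b1"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(6, (30, 6))
        genes = ["a1", "a2", "b1", "b2", "c1", "c2"]
        a = rz.normalize(make_adata(counts, genes=genes))
        rep = rz.marker_correlation(a, panel_small())
        X = np.asarray(a.X)
        for i, gi in enumerate(genes):
            for j, gj in enumerate(genes):
                want = pearsonr(rankdata(X[:, i]), rankdata(X[:, j])).statistic
                assert rep.matrix.loc[gi, gj] == pytest.approx(want, abs=1e-12)

    def test_constant_gene_reported_missing(self, caplog):
        counts = np.ones((10, 6), dtype=int) * 5
        counts[:, 1:] += np.random.default_rng(0).poisson(3, (10, 5))
        a = rz.normalize(make_adata(counts, genes=["a1", "a2", "b1", "b2", "c1", "c2"]))
        with caplog.at_level("WARNING"):
            rep = rz.marker_correlation(a, panel_small())
        # a1 has constant counts but normalization by unequal totals can
        # de-constant it; force a strictly constant normalized gene instead
        X = np.asarray(a.X)
        X[:, 0] = 1.0
        a.X = X
        rep = rz.marker_correlation(a, panel_small())
        off = rep.matrix.loc["a1"].drop("a1")
        assert off.isna().all()
        assert rep.matrix.loc["a1", "a1"] == 1.0

    def test_requires_three_spots(self):
        a = rz.normalize(make_adata(np.ones((2, 6), dtype=int),
                                    genes=["a1", "a2", "b1", "b2", "c1", "c2"]))
        with pytest.raises(InvalidConfigurationError):
            rz.marker_correlation(a, panel_small())

    def test_invariant_to_monotone_gene_transform(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(6, (25, 6))
        genes = ["a1", "a2", "b1", "b2", "c1", "c2"]
        a = rz.normalize(make_adata(counts, genes=genes))
        rep1 = rz.marker_correlation(a, panel_small())
        b = a.copy()
        b.X = np.exp(np.asarray(a.X)) ** 1.3  # strictly monotone per gene
        rep2 = rz.marker_correlation(b, panel_small())
        assert np.allclose(rep1.matrix, rep2.matrix, equal_nan=True)


class TestCollapseCorrelationTest:
    def test_identical_datasets_statistic_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(6, (40, 6))
        genes = ["a1", "a2", "b1", "b2", "c1", "c2"]
        a = rz.normalize(make_adata(counts, genes=genes))
        res = rz.collapse_correlation_test(a, a.copy(), panel_small(), n_perm=49, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.05

    def test_organized_vs_collapsed_direction(self):
        to = rz.simulate_tissue(seed=2, condition="organized")
        tc = rz.simulate_tissue(seed=1002, condition="collapsed")
        res = rz.collapse_correlation_test(
            rz.normalize(to.adata), rz.normalize(tc.adata), to.panel,
            n_perm=199, seed=2,
        )
        assert res.statistic > 0
        assert res.p_value < 0.05


class TestRadialDensity:
    def geometry(self):
        return rz.DiskGeometry(np.array([[0.0, 0.0]]), np.array([300.0]))

    def test_no_points_zero_density(self):
        pts = pd.DataFrame(columns=["x_um", "y_um", "cell_class"])
        prof = rz.radial_density(pts, self.geometry())
        assert len(prof.table) == 0

    def test_boundary_point_falls_in_innermost_inside_bin(self):
        pts = pd.DataFrame({"x_um": [300.0], "y_um": [0.0], "cell_class": ["X"]})
        prof = rz.radial_density(pts, self.geometry())
        row = prof.table[prof.table["count"] > 0].iloc[0]
        assert (row["lo_um"], row["hi_um"]) == (-50.0, 0.0)

    def test_counts_conserved_with_overflow(self):
        rng = np.random.default_rng(8)
        pts = pd.DataFrame({
            "x_um": rng.uniform(-2000, 2000, 500),
            "y_um": rng.uniform(-2000, 2000, 500),
            "cell_class": "X",
        })
        prof = rz.radial_density(pts, self.geometry())
        assert prof.table["count"].sum() + prof.overflow["X"] == 500

    def test_analytic_band_areas(self):
        g = self.geometry()
        assert g.band_area_um2(0.0, 50.0) == pytest.approx(np.pi * (350**2 - 300**2))
        assert g.band_area_um2(-100.0, -50.0) == pytest.approx(np.pi * (250**2 - 200**2))

    def test_lattice_geometry_band_area_is_tile_count(self):
        t = rz.simulate_tissue(seed=1)
        core = list(t.truth.core_spot_ids())
        field = rz.signed_distance(t.lattice, core)
        g = rz.LatticeGeometry(t.lattice, field)
        d = field["d_um"].to_numpy()
        n = int(((d > 0) & (d <= 100)).sum())
        assert g.band_area_um2(0.0, 100.0) == pytest.approx(n * t.lattice.tile_area_um2)


class TestMeanBoundaryDistance:
    def geometry(self):
        return rz.DiskGeometry(np.array([[0.0, 0.0]]), np.array([100.0]))

    def pts(self, ds):
        # place points along +x so signed distance is x - 100
        return pd.DataFrame({"x_um": [100.0 + d for d in ds], "y_um": 0.0,
                             "cell_class": "X"})

    def test_simple_mean(self):
        assert rz.mean_boundary_distance(self.pts([100.0, 300.0]), self.geometry(), "X") \
            == pytest.approx(200.0)

    def test_symmetric_points_average_zero(self):
        assert rz.mean_boundary_distance(self.pts([100.0, -100.0]), self.geometry(), "X") \
            == pytest.approx(0.0)

    def test_out_of_range_returns_missing(self):
        assert rz.mean_boundary_distance(self.pts([700.0]), self.geometry(), "X") is None
        assert rz.mean_boundary_distance(self.pts([100.0]), self.geometry(), "Y") is None

    def test_zone_c_cells_sit_in_the_periphery(self):
        # cells planted only in zone C must average inside [w_B, w_C]
        for seed in range(20):
            t = rz.simulate_tissue(seed=seed,
                                   cell_density_per_zone={"C": {"C": 150.0}})
            m = rz.mean_boundary_distance(t.cells, t.truth.geometry, "C")
            assert 100.0 <= m <= 440.0, f"seed {seed}: mean {m}"


class TestProximityFraction:
    def test_half_within_cutoff(self):
        X = np.array([[10.0, 0.0], [30.0, 0.0]])
        Y = np.array([[0.0, 0.0]])
        res = rz.proximity_fraction(X, Y, d_max_um=20.0)
        assert res.fraction == pytest.approx(0.5)
        assert res.p_value is None

    def test_identical_positions_fraction_one(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(0, 100, (10, 2))
        res = rz.proximity_fraction(Y, Y, d_max_um=1.0)
        assert res.fraction == 1.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        X, Y = rng.uniform(0, 500, (40, 2)), rng.uniform(0, 500, (15, 2))
        fracs = [rz.proximity_fraction(X, Y, d_max_um=d).fraction
                 for d in (5, 20, 50, 100, 250)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_reference_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            rz.proximity_fraction(np.ones((2, 2)), np.empty((0, 2)))

    def test_enrichment_detected_in_planted_clustering(self):
        # X placed 10x denser within 20 um of Y than elsewhere; competitor
        # class uniform: the relabeling null must flag enrichment
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.uniform(0, 1000, (50, 2))
            from scipy.spatial import cKDTree
            prop = rng.uniform(0, 1000, (1200, 2))
            d, _ = cKDTree(Y).query(prop)
            keep = rng.uniform(size=1200) < np.where(d <= 20.0, 1.0, 0.1)
            X = prop[keep][:150]
            other = rng.uniform(0, 1000, (150, 2))
            res = rz.proximity_fraction(X, Y, other, d_max_um=20.0, n_perm=199, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 18
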