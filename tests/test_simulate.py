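import numpy as np
import pandas as pd
import pytest

import rizmap as rz
from rizmap.errors import InfeasibleGeometryError, InvalidConfigurationError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"zone_width_B_um": 500.0, "zone_width_C_um": 440.0},
            {"mu_high": 1.0, "mu_low": 2.0},
            {"mu_low": 0.0},
            {"nb_dispersion": -1.0},
            {"condition": "shuffled"},
            {"lesion_radius_um": (0.0, 100.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigurationError):
            rz.SynthConfig(**kwargs)

    def test_equal_means_allowed_degenerate_snr(self):
        # mu_high == mu_low is the documented zero-signal degenerate case
        cfg = rz.SynthConfig(mu_high=2.0, mu_low=2.0, n_rows=12, n_cols=12,
                             lesion_radius_um=(120.0, 120.0), n_lesions=0)
        t = rz.simulate_tissue(cfg)
        mu = t.adata.layers["counts"].toarray().mean()
        assert mu == pytest.approx(2.0, rel=0.1)


class TestPlantLesions:
    def test_no_lesions_all_none(self):
        t = rz.simulate_tissue(seed=0, n_lesions=0)
        assert (t.truth.true_zone_per_spot == "none").all()
        assert np.isinf(t.truth.spot_truth["d_um"]).all()

    def test_core_is_disk_membership(self):
        t = rz.simulate_tissue(seed=2, lesion_radius_um=(200.0, 200.0))
        center = t.truth.lesion_centers[0]
        dist = np.linalg.norm(t.lattice.coords() - center, axis=1)
        expected_a = dist <= 200.0
        assert np.array_equal((t.truth.true_zone_per_spot == "A").to_numpy(), expected_a)

    def test_two_lesion_separation_over_seeds(self):
        lat = rz.generate_lattice(40, 40, "hex", 100.0)
        for seed in range(50):
            cfg = rz.SynthConfig(n_lesions=2, lesion_radius_um=(200.0, 200.0),
                                 min_separation_um=1500.0, seed=seed)
            truth = rz.plant_lesions(lat, cfg)
            c = truth.lesion_centers
            assert np.linalg.norm(c[0] - c[1]) >= 1500.0

    def test_disk_plus_periphery_fits_in_bbox(self):
        t = rz.simulate_tissue(seed=5)
        xmin, ymin, xmax, ymax = t.lattice.bounding_box
        (cx, cy), r = t.truth.lesion_centers[0], t.truth.lesion_radii[0]
        margin = r + t.config.zone_width_C_um
        assert xmin + margin <= cx <= xmax - margin
        assert ymin + margin <= cy <= ymax - margin

    def test_infeasible_geometry_names_constraint(self):
        lat = rz.generate_lattice(10, 10, "hex", 100.0)
        with pytest.raises(InfeasibleGeometryError, match="bounding box"):
            rz.plant_lesions(lat, rz.SynthConfig(n_rows=10, n_cols=10,
                                                 lesion_radius_um=(800.0, 800.0)))
        with pytest.raises(InfeasibleGeometryError, match="separation"):
            big = rz.generate_lattice(40, 40, "hex", 100.0)
            rz.plant_lesions(big, rz.SynthConfig(n_lesions=3, min_separation_um=50000.0,
                                                 lesion_radius_um=(200.0, 200.0)))


class TestSimulateCounts:
    def test_negative_binomial_moments(self):
        # 25 spots x 1000 background genes, all at NB(mu_low=2, theta=2):
        # i.i.d. draws, so the empirical moments must match mu and
        # mu + mu^2/theta within 15%
        t = rz.simulate_tissue(seed=3, n_rows=5, n_cols=5, n_lesions=0,
                               n_background_genes=1000)
        bg = t.adata[:, [g for g in t.adata.var_names if g.startswith("Bg")]]
        x = bg.layers["counts"].toarray().ravel()
        assert x.mean() == pytest.approx(2.0, rel=0.15)
        assert x.var() == pytest.approx(2.0 + 4.0 / 2.0, rel=0.15)

    def test_organized_zone_means(self):
        # law of large numbers over >= 500 zone-A gene/spot draws
        vals, low_vals = [], []
        for seed in range(6):
            t = rz.simulate_tissue(seed=seed)
            counts = t.adata.layers["counts"].toarray()
            a_mask = (t.truth.true_zone_per_spot == "A").to_numpy()
            a_cols = [list(t.adata.var_names).index(g) for g in t.panel["A"]]
            vals.append(counts[np.ix_(a_mask, a_cols)].ravel())
            low_vals.append(counts[np.ix_(~a_mask, a_cols)].ravel())
        vals = np.concatenate(vals)
        assert len(vals) >= 500
        assert vals.mean() == pytest.approx(16.0, rel=0.1)
        assert np.concatenate(low_vals).mean() == pytest.approx(2.0, rel=0.1)

    def test_collapsed_zone_c_signal_vanishes(self):
        vals = []
        for seed in range(6):
            t = rz.simulate_tissue(seed=seed, condition="collapsed")
            counts = t.adata.layers["counts"].toarray()
            c_mask = (t.truth.true_zone_per_spot == "C").to_numpy()
            c_cols = [list(t.adata.var_names).index(g) for g in t.panel["C"]]
            vals.append(counts[np.ix_(c_mask, c_cols)].ravel())
        assert np.concatenate(vals).mean() == pytest.approx(2.0, rel=0.1)

    def test_collapsed_ab_intermix(self):
        t = rz.simulate_tissue(seed=4, condition="collapsed")
        counts = t.adata.layers["counts"].toarray()
        ab_mask = t.truth.true_zone_per_spot.isin(["A", "B"]).to_numpy()
        for zone in ("A", "B"):
            cols = [list(t.adata.var_names).index(g) for g in t.panel[zone]]
            assert counts[np.ix_(ab_mask, cols)].mean() == pytest.approx(9.0, rel=0.25)


class TestSimulateCellPoints:
    def test_zero_density_empty(self):
        t = rz.simulate_tissue(
            seed=0, cell_density_per_zone={z: {"X": 0.0} for z in ("A", "B", "C", "none")}
        )
        assert len(t.cells) == 0

    def test_single_zone_density_matches_annulus_area(self):
        # class planted only in zone C: expected count = intensity x analytic
        # annulus area of the planted disk
        counts = []
        for seed in range(10):
            t = rz.simulate_tissue(seed=seed,
                                   cell_density_per_zone={"C": {"C": 100.0}})
            counts.append(len(t.cells))
        r, w_b, w_c = 300.0, 100.0, 440.0
        lam = 100.0 * np.pi * ((r + w_c) ** 2 - (r + w_b) ** 2) / 1e6
        mean = np.mean(counts)
        assert abs(mean - lam) < 4 * np.sqrt(lam / len(counts))

    def test_points_inside_bounding_box(self, organized_tissue):
        xmin, ymin, xmax, ymax = organized_tissue.lattice.bounding_box
        c = organized_tissue.cells
        assert c["x_um"].between(xmin, xmax).all()
        assert c["y_um"].between(ymin, ymax).all()

    def test_invalid_density_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            rz.simulate_tissue(seed=0, cell_density_per_zone={"A": {"X": float("nan")}})


class TestDeterminismAndConsistency:
    def test_identical_config_bit_identical_output(self):
        a = rz.simulate_tissue(seed=11)
        b = rz.simulate_tissue(seed=11)
        assert np.array_equal(a.adata.layers["counts"].toarray(),
                              b.adata.layers["counts"].toarray())
        assert np.array_equal(a.truth.lesion_centers, b.truth.lesion_centers)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_seed_changes_output(self):
        a = rz.simulate_tissue(seed=11)
        b = rz.simulate_tissue(seed=12)
        assert not np.array_equal(a.adata.layers["counts"].toarray(),
                                  b.adata.layers["counts"].toarray())

    def test_truth_consistent_with_expected_zones(self, organized_tissue):
        # the generator's zone labels must equal the zone model applied to
        # the planted analytic distance field (cross-module self-consistency)
        truth = organized_tissue.truth
        zmap = rz.expected_zones(truth.spot_truth, truth.zone_width_B_um,
                                 truth.zone_width_C_um)
        assert (zmap.zones == truth.true_zone_per_spot).all()
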