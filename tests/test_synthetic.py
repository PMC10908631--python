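"""Generator contracts: determinism, point-process statistics, rendering."""

import numpy as np
import pandas as pd
import pytest

from spatialtme.intensity import mean_signal_intensity
from spatialtme.synthetic import (CELL_TYPES, PANEL, ClusterParams,
                                  GeneratorConfig, render_sample_images,
                                  simulate_cohort, simulate_sample)


class TestSimulateSample:
    def test_same_seed_bit_identical(self, default_config):
        a = simulate_sample(default_config, "NT", seed=7)
        b = simulate_sample(default_config, "NT", seed=7)
        pd.testing.assert_frame_equal(a.cells, b.cells, check_exact=True)
        pd.testing.assert_frame_equal(a.ground_truth.table, b.ground_truth.table,
                                      check_exact=True)
        assert a.metadata == b.metadata

    def test_different_seeds_differ(self, default_config):
        a = simulate_sample(default_config, "NT", seed=7)
        b = simulate_sample(default_config, "NT", seed=8)
        assert not a.cells.equals(b.cells)

    def test_tumor_count_poisson_oracle(self):
        # homogeneous Poisson process: count ~ Poisson(lambda * A)
        cfg = GeneratorConfig(
            roi_width=1000.0, roi_height=1000.0,
            densities={"tumor": 0.002, "myeloid": 0, "cd4t": 0, "cd8t": 0,
                       "neutrophil": 0},
            neutrophil_cluster_params={
                "NT": ClusterParams(n_clusters=0),
                "IT": ClusterParams(n_clusters=0)})
        lam = 0.002 * 1000 * 1000
        for seed in range(5):
            res = simulate_sample(cfg, "NT", seed=seed)
            n_tumor = int((res.ground_truth.table["true_type"] == "tumor").sum())
            assert abs(n_tumor - lam) <= 3 * np.sqrt(lam)

    def test_nt_neutrophil_fraction_exceeds_it(self, default_config):
        nt = simulate_sample(default_config, "NT", seed=3)
        it = simulate_sample(default_config, "IT", seed=3)
        f = {}
        for name, s in (("NT", nt), ("IT", it)):
            counts = s.ground_truth.type_counts()
            f[name] = counts["neutrophil"] / counts.sum()
        assert f["NT"] > f["IT"]

    def test_cluster_ids_reference_centers(self, default_config, nt_sample):
        gt = nt_sample.ground_truth.table
        n_clusters = default_config.neutrophil_cluster_params["NT"].n_clusters
        assert set(gt["cluster_id"]) <= set(range(n_clusters + 1))
        # cluster members are neutrophils only
        assert (gt.loc[gt["cluster_id"] > 0, "true_type"] == "neutrophil").all()

    def test_marker_logmean_converges(self):
        # sample mean of log intensities within 3*sigma/sqrt(n) of mu
        cfg = GeneratorConfig(
            densities={"tumor": 0.004, "myeloid": 0, "cd4t": 0, "cd8t": 0,
                       "neutrophil": 0},
            neutrophil_cluster_params={"IT": ClusterParams(n_clusters=0),
                                       "NT": ClusterParams(n_clusters=0)},
            treatment_effects={"NT": {}, "IT": {}})
        res = simulate_sample(cfg, "IT", seed=11)
        n = len(res.cells)
        for marker in ("E-Cadherin", "CD11b", "Ki67"):
            mu, sigma = cfg.marker_model[marker]["tumor"]
            assert abs(np.log(res.cells[marker]).mean() - mu) < 3 * sigma / np.sqrt(n)

    def test_invalid_group_rejected(self, default_config):
        with pytest.raises(ValueError, match="group"):
            simulate_sample(default_config, "XX", seed=0)

    def test_nonpositive_roi_rejected(self):
        cfg = GeneratorConfig(roi_width=0.0)
        with pytest.raises(ValueError, match="ROI"):
            simulate_sample(cfg, "NT", seed=0)

    def test_cell_cap_enforced(self):
        cfg = GeneratorConfig(max_cells=100)
        with pytest.raises(ValueError, match="max_cells"):
            simulate_sample(cfg, "NT", seed=0)

    def test_cluster_radius_bound(self):
        cfg = GeneratorConfig(neutrophil_cluster_params={
            "NT": ClusterParams(cluster_radius=400.0),
            "IT": ClusterParams()})
        with pytest.raises(ValueError, match="radius"):
            simulate_sample(cfg, "NT", seed=0)

    def test_panel_columns_present(self, nt_sample):
        assert set(PANEL) <= set(nt_sample.cells.columns)
        assert (nt_sample.cells[list(PANEL)].to_numpy() >= 0).all()


class TestSimulateCohort:
    @pytest.mark.parametrize("n_per_group,expected", [(3, 6), (1, 2)])
    def test_sizes_and_balance(self, default_config, n_per_group, expected):
        cohort = simulate_cohort(default_config, n_per_group=n_per_group, seed=0)
        assert len(cohort.samples) == expected
        groups = cohort.metadata["group"].value_counts()
        assert groups["NT"] == groups["IT"] == n_per_group

    def test_samples_pairwise_distinct(self, cohort):
        tables = [s.cells.drop(columns=["sample_id"]) for s in cohort.samples]
        for i in range(len(tables)):
            for j in range(i + 1, len(tables)):
                assert not tables[i].equals(tables[j])

    def test_reproducible(self, default_config):
        a = simulate_cohort(default_config, 2, seed=9)
        b = simulate_cohort(default_config, 2, seed=9)
        pd.testing.assert_frame_equal(a.cells, b.cells, check_exact=True)

    def test_invalid_n_rejected(self, default_config):
        with pytest.raises(ValueError):
            simulate_cohort(default_config, n_per_group=0, seed=0)

    def test_ground_truth_one_label_per_cell(self, cohort):
        gt = cohort.ground_truth
        assert gt["true_type"].isin(CELL_TYPES).all()
        assert not gt.duplicated(["sample_id", "cell_id"]).any()
        assert len(gt) == len(cohort.cells)


class TestRendering:
    def test_single_cell_exact_pixels(self):
        cells = pd.DataFrame({"sample_id": "s", "cell_id": [1], "x": [10.0],
                              "y": [10.0], "area": [4.0], "CD3": [2.0]})
        mask, channels = render_sample_images(cells, 20, 20, markers=["CD3"],
                                              background=0.0)
        assert (mask == 1).sum() == 4
        assert set(np.unique(mask)) == {0, 1}
        assert np.all(channels["CD3"][mask == 1] == 2.0)
        assert np.all(channels["CD3"][mask == 0] == 0.0)

    def test_empty_table(self):
        cells = pd.DataFrame(columns=["sample_id", "cell_id", "x", "y", "area", "CD3"])
        mask, channels = render_sample_images(cells, 10, 10, markers=["CD3"],
                                              background=0.5)
        assert mask.shape == (10, 10)
        assert not mask.any()
        assert np.all(channels["CD3"] == np.float32(0.5))

    def test_roundtrip_msi_exact_nonoverlapping(self):
        # well-spaced cells: constant fill makes the per-cell mean exact
        rng = np.random.default_rng(0)
        n = 16
        gx, gy = np.meshgrid(np.arange(4), np.arange(4))
        cells = pd.DataFrame({
            "sample_id": "s", "cell_id": np.arange(1, n + 1),
            "x": gx.ravel() * 25.0 + 12.0, "y": gy.ravel() * 25.0 + 12.0,
            "area": rng.uniform(20, 60, n).round(),
            "Ly6G": rng.lognormal(1, 0.5, n)})
        mask, channels = render_sample_images(cells, 100, 100, markers=["Ly6G"],
                                              background=0.25)
        table = mean_signal_intensity(mask, channels["Ly6G"])
        by_label = table.set_index("label")
        for row in cells.itertuples(index=False):
            assert by_label.at[row.cell_id, "n_pixels"] == round(row.area)
            assert by_label.at[row.cell_id, "msi"] == np.float32(row.Ly6G)

    def test_pixel_count_conservation(self, nt_sample, default_config):
        mask, _ = render_sample_images(nt_sample.cells,
                                       default_config.roi_width,
                                       default_config.roi_height, markers=[])
        counts = np.bincount(mask.ravel())
        assert counts.sum() == mask.size

    def test_overlap_resolved_to_lower_id(self):
        cells = pd.DataFrame({"sample_id": "s", "cell_id": [1, 2],
                              "x": [10.0, 11.0], "y": [10.0, 10.0],
                              "area": [50.0, 50.0], "CD3": [1.0, 2.0]})
        mask, _ = render_sample_images(cells, 20, 20, markers=["CD3"])
        assert (mask == 1).sum() == 50          # lower id keeps all its pixels
        assert 0 < (mask == 2).sum() < 50       # higher id loses the contested ones

    def test_centroid_outside_roi_rejected(self):
        cells = pd.DataFrame({"sample_id": "s", "cell_id": [1], "x": [25.0],
                              "y": [5.0], "area": [4.0]})
        with pytest.raises(ValueError, match="outside"):
            render_sample_images(cells, 20, 20, markers=[])

    def test_duplicate_cell_id_rejected(self):
        cells = pd.DataFrame({"sample_id": "s", "cell_id": [1, 1],
                              "x": [5.0, 6.0], "y": [5.0, 6.0],
                              "area": [4.0, 4.0]})
        with pytest.raises(ValueError, match="duplicate"):
            render_sample_images(cells, 20, 20, markers=[])
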