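import numpy as np
import pytest

from sofiquant.simulator import (GroundTruth, PhotokineticsModel,
                                 make_ground_truth, render_sequence,
                                 run_scenarios, simulate_sequence,
                                 simulate_traces)
from sofiquant.stack_io import AcquisitionConfig


class TestGroundTruth:
    def test_default_layout_ten_hdrs_on_3um_field(self):
        gt = make_ground_truth(seed=1)
        assert len(gt.hdr_specs) == 10
        assert gt.field_um == 3.0

    def test_hdrs_inside_field_and_disjoint(self):
        gt = make_ground_truth(n_hdrs=10, diameter_nm=180.0,
                               hdr_density_per_um2=3000.0, seed=2)
        field_nm = 3000.0
        centers = [c for c, _, _ in gt.hdr_specs]
        for (x, y), d, _ in gt.hdr_specs:
            r = d / 2
            assert r <= x <= field_nm - r and r <= y <= field_nm - r
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dist = np.hypot(centers[i][0] - centers[j][0],
                                centers[i][1] - centers[j][1])
                assert dist >= 180.0  # two radii

    def test_molecule_count_matches_density(self):
        # 180 nm, 3000 /um^2 -> Poisson mean 3000*pi*0.09^2 ~ 76.3 per HDR
        gt = make_ground_truth(n_hdrs=10, diameter_nm=180.0,
                               hdr_density_per_um2=3000.0, contrast=100.0,
                               seed=3)
        per_hdr = np.bincount(gt.molecule_hdr_id[gt.molecule_hdr_id >= 0],
                              minlength=10)
        assert np.all(per_hdr > 76.3 - 4 * np.sqrt(76.3))
        assert np.all(per_hdr < 76.3 + 4 * np.sqrt(76.3))
        assert gt.background_density_per_um2 == pytest.approx(30.0)

    def test_background_molecules_outside_hdrs(self):
        gt = make_ground_truth(n_hdrs=5, diameter_nm=180.0,
                               hdr_density_per_um2=3000.0, seed=4)
        bg = gt.molecule_xy_nm[gt.molecule_hdr_id == -1]
        for (cx, cy), d, _ in gt.hdr_specs:
            dist = np.hypot(bg[:, 0] - cx, bg[:, 1] - cy)
            assert np.all(dist >= d / 2)

    def test_random_control_has_no_hdrs(self):
        gt = make_ground_truth(n_hdrs=0, diameter_nm=180.0,
                               hdr_density_per_um2=3000.0, contrast=100.0,
                               seed=5)
        assert gt.hdr_specs == []
        assert np.all(gt.molecule_hdr_id == -1)
        assert gt.n_molecules > 0

    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(contrast=0.0)


class TestTraces:
    def test_stationary_on_fraction(self):
        model = PhotokineticsModel(mean_on_frames=2.0, mean_off_frames=8.0,
                                   activation_rate_per_frame=0.0,
                                   bleach_prob_per_on_frame=0.0,
                                   brightness_photons_per_frame=100.0)
        traces = simulate_traces(300, 2000, model, seed=0)
        on_frac = (traces > 0).mean()
        # stationary occupancy 2/(2+8) = 0.2; dwell correlation inflates the
        # naive binomial SE by ~sqrt(mean cycle length)
        se = np.sqrt(0.2 * 0.8 / (300 * 2000 / 10.0))
        assert abs(on_frac - 0.2) < 4 * se

    def test_zero_brightness_silent(self):
        model = PhotokineticsModel(brightness_photons_per_frame=0.0)
        traces = simulate_traces(20, 500, model, seed=1)
        assert np.all(traces == 0)

    def test_immediate_bleach_single_on_period(self):
        model = PhotokineticsModel(mean_on_frames=3.0,
                                   activation_rate_per_frame=0.01,
                                   bleach_prob_per_on_frame=1.0,
                                   brightness_photons_per_frame=100.0)
        traces = simulate_traces(100, 3000, model, seed=2)
        for tr in traces:
            on = np.nonzero(tr)[0]
            assert len(on) <= 1  # bleaches on its first emitting frame

    def test_photon_budget(self):
        model = PhotokineticsModel(activation_rate_per_frame=0.0,
                                   bleach_prob_per_on_frame=0.0,
                                   brightness_photons_per_frame=250.0)
        traces = simulate_traces(100, 1000, model, seed=3)
        n_on = int((traces > 0).sum())
        total = traces.sum()
        assert abs(total - 250.0 * n_on) < 3 * np.sqrt(250.0 * n_on)


class TestRender:
    def test_empty_field_is_noise_only(self):
        gt = GroundTruth(molecule_xy_nm=np.zeros((0, 2)), hdr_specs=[],
                         background_density_per_um2=0.0, field_um=3.0,
                         seed=0, molecule_hdr_id=np.zeros(0, dtype=int))
        optics = AcquisitionConfig()
        seq = render_sequence(gt, np.zeros((0, 200)), optics, seed=0)
        # clipped read noise only: well under one photoelectron per pixel
        assert seq.frames.mean() < 3 * optics.read_noise_counts / optics.counts_per_pe
        assert seq.frames.std() > 0

    def test_flux_conservation_always_on_emitter(self):
        gt = GroundTruth(molecule_xy_nm=np.array([[1500.0, 1500.0]]),
                         hdr_specs=[], background_density_per_um2=0.0,
                         field_um=3.0, seed=0,
                         molecule_hdr_id=np.array([0]))
        optics = AcquisitionConfig(offset_counts=0.0,
                                   read_noise_counts=1e-9)
        T, photons = 400, 300.0
        traces = np.full((1, T), photons)
        seq = render_sequence(gt, traces, optics, seed=1,
                              detection_efficiency=1.0)
        per_frame = seq.frames.sum(axis=(1, 2))
        se = np.sqrt(photons / T)
        assert abs(per_frame.mean() - photons) < 3 * se + 1.0

    def test_doubling_gain_doubles_raw_counts(self, tmp_path):
        from sofiquant.stack_io import write_stack
        import tifffile
        gt = GroundTruth(molecule_xy_nm=np.array([[1500.0, 1500.0]]),
                         hdr_specs=[], background_density_per_um2=0.0,
                         field_um=3.0, seed=0, molecule_hdr_id=np.array([0]))
        traces = np.full((1, 100), 200.0)
        means = {}
        for gain in (150.0, 300.0):
            optics = AcquisitionConfig(em_gain=gain, offset_counts=100.0,
                                       read_noise_counts=1e-9)
            seq = render_sequence(gt, traces, optics, seed=2)
            path = tmp_path / f"g{gain}.tif"
            write_stack(path, seq, optics)
            raw = tifffile.imread(path).astype(float)
            means[gain] = raw.mean() - optics.offset_counts
        assert means[300.0] == pytest.approx(2 * means[150.0], rel=0.05)

    def test_determinism_bit_exact(self):
        gt = make_ground_truth(n_hdrs=2, diameter_nm=120.0,
                               hdr_density_per_um2=1000.0, seed=7)
        model = PhotokineticsModel()
        optics = AcquisitionConfig()
        a = simulate_sequence(gt, 200, model, optics, seed=42)
        b = simulate_sequence(gt, 200, model, optics, seed=42)
        assert np.array_equal(a.frames, b.frames)


class TestRunScenarios:
    def test_grid_product_and_manifest(self, tmp_path):
        manifest = run_scenarios(tmp_path, diameters_nm=[60, 120, 180],
                                 densities_per_um2=[500, 1750, 3000],
                                 contrasts=[20, 50, 100], layouts=[10],
                                 replicates=1, T=20, seed=0)
        assert len(manifest) == 27
        assert (tmp_path / "manifest.csv").exists()
        for _, row in manifest.iterrows():
            assert (tmp_path / row["stack"]).exists()
            assert (tmp_path / row["truth"]).exists()

    def test_zero_replicates_empty_manifest(self, tmp_path):
        manifest = run_scenarios(tmp_path, diameters_nm=[120],
                                 densities_per_um2=[1000], contrasts=[50],
                                 replicates=0, T=10, seed=0)
        assert len(manifest) == 0

    def test_same_seed_identical_outputs(self, tmp_path):
        import hashlib
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            run_scenarios(out, diameters_nm=[120], densities_per_um2=[1000],
                          contrasts=[50], replicates=1, T=15, seed=9)
            digests.append(hashlib.sha256(
                (out / "scenario_0000_stack.tif").read_bytes()).hexdigest())
        assert digests[0] == digests[1]
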