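"""Phantom construction, design randomization and run simulation."""

from collections import Counter

import numpy as np
import pytest

from mionmap import hemodynamics, phantom_sim
from mionmap.phantom_sim import (
    GroundTruth,
    ProtocolConfig,
    RegionSpec,
    VolumeGrid,
    default_catalog,
    make_phantom,
    make_run_design,
    simulate_run,
)


class TestVolumeGrid:
    def test_affine_encodes_size_and_origin(self):
        g = VolumeGrid((10, 12, 8), 1.5, (-7.5, 0.0, 3.0))
        assert np.allclose(np.diag(g.affine), [1.5, 1.5, 1.5, 1.0])
        assert np.allclose(g.affine[:3, 3], [-7.5, 0.0, 3.0])

    @pytest.mark.parametrize("dims,vox", [((4, 10, 10), 1.5), ((10, 10, 10), 0.0)])
    def test_invalid_grid_rejected(self, dims, vox):
        with pytest.raises(ValueError):
            VolumeGrid(dims, vox)


class TestPhantom:
    def test_default_phantom_contents(self, atlas):
        assert len(atlas.region_table) >= 6
        assert "A1-like" in atlas.region_table
        assert atlas.white_mask.sum() > 0 and atlas.csf_mask.sum() > 0
        # every named region code appears and regions are disjoint tissue codes
        for name, code in atlas.region_table.items():
            assert np.any(atlas.labels == code), name
        classes = atlas.gray_mask.astype(int) + atlas.white_mask + atlas.csf_mask
        assert classes.max() == 1

    def test_overlapping_regions_error_names_both(self):
        grid = VolumeGrid((24, 24, 18))
        specs = [
            RegionSpec("r-one", ((12, 12, 9),), 2.0),
            RegionSpec("r-two", ((13, 12, 9),), 2.0),
        ]
        with pytest.raises(ValueError, match="r-one.*r-two|r-two.*r-one"):
            make_phantom(grid, specs)

    def test_region_outside_grid_errors(self):
        grid = VolumeGrid((24, 24, 18))
        with pytest.raises(ValueError, match="fit inside"):
            make_phantom(grid, [RegionSpec("edge", ((0, 0, 0),), 2.0)])

    def test_empty_region_spec_gives_tissue_only_atlas(self):
        atlas = make_phantom(VolumeGrid((24, 24, 18)), [])
        assert atlas.region_table == {}
        assert set(np.unique(atlas.labels)) == {
            phantom_sim.BACKGROUND,
            phantom_sim.GRAY,
            phantom_sim.WHITE,
            phantom_sim.CSF,
        }


def test_catalog_structure(catalog):
    t = catalog.table
    assert len(t) == 48
    assert len(catalog.subcategories) == 8
    assert all(len(catalog.stimuli_of(s)) == 6 for s in catalog.subcategories)
    mains = set(catalog.main_of.values())
    assert mains == {"macaque_vocal", "non_vocal"}


class TestRunDesign:
    def test_invariants_across_seeds(self, catalog):
        protocol = ProtocolConfig()
        for seed in range(300):
            d = make_run_design(seed, protocol, catalog)
            counts = Counter(b.condition for b in d.blocks)
            assert counts.pop("silence") == 16
            assert sum(counts.values()) == 32
            assert set(counts.values()) == {4}
            assert d.n_volumes == 336
            # acquisition clusters strictly increasing and non-overlapping
            times = d.volume_times
            assert np.all(np.diff(times) > 0)
            for i, (blk, cluster) in enumerate(zip(d.blocks, d.clusters)):
                gap_start = i * protocol.cycle_duration_s
                if blk.condition == "silence":
                    continue
                assert 0.100 <= blk.jitter_s <= 0.250
                # the block starts inside the scanner-silent gap
                assert gap_start < blk.onset_s < cluster.start_time_s
                assert blk.onset_s + blk.duration_s <= cluster.start_time_s + 1e-9
                assert len(blk.stimulus_ids) == 6

    def test_same_seed_identical(self, catalog):
        assert make_run_design(7, catalog=catalog) == make_run_design(7, catalog=catalog)
        assert make_run_design(7, catalog=catalog) != make_run_design(8, catalog=catalog)

    def test_zero_jitter_degenerate(self, catalog):
        protocol = ProtocolConfig(jitter_min_s=0.0, jitter_max_s=0.0)
        d = make_run_design(3, protocol, catalog)
        for i, blk in enumerate(d.blocks):
            if blk.condition != "silence":
                assert blk.onset_s == pytest.approx(i * protocol.cycle_duration_s)

    def test_block_too_long_for_gap_errors(self, catalog):
        protocol = ProtocolConfig(gap_s=2.0)
        with pytest.raises(ValueError, match="cannot fit"):
            make_run_design(0, protocol, catalog)

    def test_run_duration_follows_schedule(self, catalog):
        d = make_run_design(0, catalog=catalog)
        assert d.run_duration_s == pytest.approx(48 * (3.5 + 7 * 0.646))


class TestSimulateRun:
    def test_null_truth_gives_constant_baseline(self, atlas, design, rf):
        truth = GroundTruth(
            amplitudes={},
            ar1_rho=0.0,
            white_sd_pct=0.0,
            drift_coeffs_pct=(0.0,),
            n_white_components=0,
            n_csf_components=0,
        )
        img, _ = simulate_run(atlas, design, truth, rf, seed=0)
        brain = atlas.brain_mask
        assert np.all(img.data[brain] == truth.baseline)
        assert np.all(img.data[~brain] == 0.0)

    def test_contrast_agent_sign_reversal(self, atlas, design, rf, noise_free_truth):
        """Positive neural amplitude lowers the measured intensity."""
        img, _ = simulate_run(atlas, design, noise_free_truth, rf, seed=0)
        a1 = atlas.region_mask("A1-like")
        baseline = noise_free_truth.baseline
        assert img.data[a1].min() < baseline - 1.0
        assert img.data[a1].max() <= baseline + 1e-9
        plain_gray = atlas.labels == phantom_sim.GRAY
        assert np.all(img.data[plain_gray] == baseline)

    def test_same_seed_bit_identical(self, atlas, design, rf, catalog):
        truth = phantom_sim.default_truth(catalog)
        a, _ = simulate_run(atlas, design, truth, rf, seed=5)
        b, _ = simulate_run(atlas, design, truth, rf, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_unknown_region_errors(self, atlas, design, rf):
        truth = GroundTruth(amplitudes={"nonexistent": {"*": 1.0}})
        with pytest.raises(KeyError, match="nonexistent"):
            simulate_run(atlas, design, truth, rf, seed=0)

    def test_timestamps_match_schedule(self, simulated_run, design):
        img, _, _ = simulated_run
        assert np.array_equal(img.timestamps_s, design.volume_times)
        assert img.data.shape[-1] == design.n_volumes

    def test_noise_mean_and_autocorrelation(self, atlas, design, rf):
        """Pure-noise runs: temporal mean near baseline, lag-1 autocorrelation
        near the configured rho."""
        rho = 0.3
        truth = GroundTruth(
            amplitudes={},
            ar1_rho=rho,
            white_sd_pct=0.5,
            drift_coeffs_pct=(0.0,),
            n_white_components=0,
            n_csf_components=0,
        )
        img, _ = simulate_run(atlas, design, truth, rf, seed=9)
        brain = atlas.brain_mask
        x = img.data[brain] - truth.baseline
        n_t = x.shape[-1]
        sd = truth.white_sd_pct / 100 * truth.baseline
        # AR(1)-corrected standard error of the temporal mean
        se = sd / np.sqrt(n_t) * np.sqrt((1 + rho) / (1 - rho))
        frac_within = np.mean(np.abs(x.mean(axis=-1)) <= 3 * se)
        assert frac_within >= 0.98
        num = np.einsum("ij,ij->i", x[:, 1:], x[:, :-1])
        den = np.einsum("ij,ij->i", x, x)
        assert abs(np.mean(num / den) - rho) < 0.05

    def test_nuisance_confined_to_compartments_by_default(self, atlas, design, rf):
        truth = GroundTruth(
            amplitudes={},
            ar1_rho=0.0,
            white_sd_pct=0.0,
            drift_coeffs_pct=(0.0,),
            n_white_components=2,
            n_csf_components=2,
            nuisance_sd_pct=2.0,
        )
        img, _ = simulate_run(atlas, design, truth, rf, seed=3)
        gray = atlas.gray_mask
        assert np.all(img.data[gray] == truth.baseline)
        assert img.data[atlas.white_mask].std() > 0
        assert img.data[atlas.csf_mask].std() > 0


class TestSimulateCohort:
    @pytest.fixture()
    def tiny_protocol(self):
        return ProtocolConfig(n_cycles=24, n_stimulus_blocks=16, n_silence_blocks=8)

    def test_writes_expected_files(self, tmp_path, small_atlas, tiny_protocol):
        truth = phantom_sim.default_truth()
        manifest = phantom_sim.simulate_cohort(
            2, 3, truth, seed=1, out_dir=tmp_path, atlas=small_atlas,
            protocol=tiny_protocol,
        )
        assert len(manifest) == 6
        for row in manifest.itertuples(index=False):
            assert (tmp_path / row.image).exists()
            assert (tmp_path / row.events).exists()
        assert (tmp_path / "atlas.nii.gz").exists()
        assert (tmp_path / "manifest.tsv").exists()

    def test_rerun_same_seed_identical(self, tmp_path, small_atlas, tiny_protocol):
        truth = phantom_sim.default_truth()
        m1 = phantom_sim.simulate_cohort(
            1, 2, truth, seed=4, out_dir=tmp_path / "a", atlas=small_atlas,
            protocol=tiny_protocol,
        )
        m2 = phantom_sim.simulate_cohort(
            1, 2, truth, seed=4, out_dir=tmp_path / "b", atlas=small_atlas,
            protocol=tiny_protocol,
        )
        assert m1.equals(m2)
        from mionmap import cli_io

        a, _ = cli_io.read_volume(tmp_path / "a" / m1.iloc[0]["image"], expect_4d=True)
        b, _ = cli_io.read_volume(tmp_path / "b" / m2.iloc[0]["image"], expect_4d=True)
        assert np.array_equal(a, b)

    def test_zero_subjects_error(self, tmp_path):
        with pytest.raises(ValueError):
            phantom_sim.simulate_cohort(
                0, 2, phantom_sim.default_truth(), seed=0, out_dir=tmp_path
            )

    def test_drawn_run_counts_have_median_12(self):
        rng = np.random.default_rng(0)
        counts = phantom_sim._draw_run_counts(rng, 11)
        assert np.median(counts) == 12
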