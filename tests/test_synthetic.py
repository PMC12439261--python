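"""Tests of the synthetic ground-truth generator: vessel trees, bubble
transport, frame rendering and the histology cohort."""

import numpy as np
import pytest
from scipy import stats as sps

from lnulm.errors import InvalidParameterError, OutOfBoundsError
from lnulm.localize import FWHM_TO_SIGMA
from lnulm.synthetic import (
    AcquisitionConfig,
    SyntheticCohort,
    TruthTrack,
    default_fixture,
    draw_cohort_truth,
    generate_vessel_tree,
    motion_shifts_px,
    render_frames,
    simulate_histology_cohort,
    simulate_mb_flow,
)

EXTENT = ((400.0, 6000.0), (400.0, 6000.0))


class TestVesselTree:
    def test_single_trunk_at_generation_zero(self):
        tree = generate_vessel_tree(EXTENT, max_generation=0, seed=0)
        assert len(tree.segments) == 1
        seg = tree.segments[0]
        assert seg.vessel_class == "trunk"
        assert np.allclose(seg.start_um, tree.hilum_um)

    def test_same_seed_reproduces_identical_tree(self):
        a = generate_vessel_tree(EXTENT, max_generation=3, seed=5)
        b = generate_vessel_tree(EXTENT, max_generation=3, seed=5)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.start_um, sb.start_um)
            assert np.array_equal(sa.end_um, sb.end_um)
            assert sa.radius_um == sb.radius_um and sa.speed_mm_s == sb.speed_mm_s

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_radius_strictly_decreases_along_every_path(self, seed):
        """Exhaustive root-to-leaf walk: radius must shrink monotonically."""
        tree = generate_vessel_tree(EXTENT, max_generation=3, seed=seed)
        paths = tree.root_to_leaf_paths()
        assert paths, "tree has no root-to-leaf path"
        for path in paths:
            radii = [s.radius_um for s in path]
            assert all(r1 > r2 for r1, r2 in zip(radii, radii[1:]))

    def test_contains_arterial_and_venous_subtrees(self):
        tree = generate_vessel_tree(EXTENT, max_generation=1, seed=3)
        classes = {s.vessel_class for s in tree.segments}
        assert {"trunk", "arterial", "venous"} <= classes

    def test_trunk_has_highest_class_mean_speed(self):
        tree = generate_vessel_tree(EXTENT, max_generation=3, seed=9)
        by_class = {}
        for s in tree.segments:
            by_class.setdefault(s.vessel_class, []).append(s.speed_mm_s)
        means = {k: np.mean(v) for k, v in by_class.items()}
        assert means["trunk"] == max(means.values())

    def test_degenerate_extent_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_vessel_tree(((0, 0), (0, 100)), max_generation=1, seed=0)


@pytest.fixture(scope="module")
def tree():
    return generate_vessel_tree(EXTENT, max_generation=2, seed=11)


class TestBubbleTransport:

    def test_per_frame_advance_matches_speed_over_frame_rate(self, tree):
        """A 5 mm/s segment at 500 Hz advances 10 μm per frame."""
        cfg = AcquisitionConfig(n_frames=100, seed=1)
        tracks = simulate_mb_flow(tree, 30, cfg, jitter_um=0.0)
        by_seg = {s.segment_id: s for s in tree.segments}
        for t in tracks:
            expect = by_seg[t.segment_id].speed_mm_s * 1000.0 / cfg.frame_rate_hz
            steps = np.linalg.norm(np.diff(t.positions_um, axis=0), axis=1)
            # interior steps advance exactly; boundary clipping may shorten ends
            assert np.allclose(np.median(steps), expect, rtol=1e-9)

    def test_zero_bubbles_gives_empty_list(self, tree):
        assert simulate_mb_flow(tree, 0, AcquisitionConfig(n_frames=10, seed=0)) == []

    def test_zero_jitter_step_speed_equals_segment_speed(self, tree):
        """Recompute step lengths from emitted positions: with no jitter every
        per-step speed equals the host segment's flow speed."""
        cfg = AcquisitionConfig(n_frames=150, seed=2)
        tracks = simulate_mb_flow(tree, 20, cfg, jitter_um=0.0)
        assert tracks
        by_seg = {s.segment_id: s for s in tree.segments}
        checked = 0
        for t in tracks:
            interior = t.step_speeds_mm_s
            # exclude steps affected by extent clipping at segment ends
            core = interior[(interior > 0.99 * interior.max())]
            assert np.allclose(core, by_seg[t.segment_id].speed_mm_s, rtol=1e-9)
            checked += 1
        assert checked > 0

    def test_truth_track_invariants(self, tree):
        cfg = AcquisitionConfig(n_frames=100, seed=5)
        for t in simulate_mb_flow(tree, 25, cfg):
            assert np.all(np.diff(t.frames) == 1), "frames must be gapless"
            assert t.true_type in (1, 2, 3)
            (a0, a1), (l0, l1) = tree.extent_um
            assert t.positions_um[:, 0].min() >= a0 and t.positions_um[:, 0].max() <= a1
            assert t.positions_um[:, 1].min() >= l0 and t.positions_um[:, 1].max() <= l1

    def test_min_separation_respected(self, tree):
        cfg = AcquisitionConfig(n_frames=100, seed=8)
        tracks = simulate_mb_flow(tree, 25, cfg, min_separation_um=250.0)
        by_frame = {}
        for t in tracks:
            for f, p in zip(t.frames, t.positions_um):
                by_frame.setdefault(int(f), []).append(p)
        for pts in by_frame.values():
            pts = np.asarray(pts)
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    assert np.hypot(*(pts[i] - pts[j])) >= 250.0

    def test_empty_tree_rejected(self):
        from lnulm.synthetic import VesselTree

        empty = VesselTree(segments=[], hilum_um=[0, 0], extent_um=EXTENT)
        with pytest.raises(InvalidParameterError):
            simulate_mb_flow(empty, 5, AcquisitionConfig(n_frames=10, seed=0))


class TestRenderFrames:
    def test_no_bubbles_no_tissue_gives_zero_stack(self):
        cfg = AcquisitionConfig(n_frames=4, rows=16, cols=16, tissue_amplitude=0.0, seed=0)
        seq = render_frames([], cfg)
        assert seq.n_frames == 4
        assert np.all(seq.frames == 0)

    def test_single_bubble_matches_closed_form_gaussian(self):
        """Pixel values equal the anisotropic Gaussian evaluated at pixel
        centers (independent evaluation of the closed form)."""
        cfg = AcquisitionConfig(n_frames=2, rows=32, cols=32, tissue_amplitude=0.0, seed=0)
        pos = np.array([[15 * 50.0, 16 * 50.0]] * 2)
        tt = TruthTrack(0, [0, 1], pos, 0, 1, cfg.frame_rate_hz)
        seq = render_frames([tt], cfg)
        sa = cfg.psf_fwhm_axial_um / FWHM_TO_SIGMA / 50.0
        sl = cfg.psf_fwhm_lateral_um / FWHM_TO_SIGMA / 50.0
        rr, cc = np.mgrid[0:32, 0:32]
        expect = np.exp(-((rr - 15.0) ** 2) / (2 * sa**2) - ((cc - 16.0) ** 2) / (2 * sl**2))
        # renderer truncates the PSF support at 6 sigma (values < 2e-8 there)
        assert np.allclose(seq.frames[0], expect, atol=2e-8)

    def test_rigid_motion_shifts_follow_the_sampled_sinusoid(self):
        """Cross-correlating rendered tissue-only frames against frame 0
        recovers the configured sinusoidal shift sequence."""
        from skimage.registration import phase_cross_correlation

        n = 16
        cfg = AcquisitionConfig(
            n_frames=n,
            rows=64,
            cols=64,
            tissue_amplitude=1.0,
            tissue_modulation=0.0,
            motion_amplitude_px=2.0,
            motion_period_s=n / 500.0,  # one full cycle over the sequence
            seed=4,
        )
        seq = render_frames([], cfg)
        expect = motion_shifts_px(cfg)
        for f in range(1, n):
            shift, _, _ = phase_cross_correlation(
                seq.frames[0], seq.frames[f], upsample_factor=20, normalization=None
            )
            est = -shift[0]  # displacement of frame f relative to frame 0
            assert est == pytest.approx(expect[f] - expect[0], abs=0.1)

    def test_track_outside_fov_raises_with_ids(self):
        cfg = AcquisitionConfig(n_frames=2, rows=16, cols=16, tissue_amplitude=0.0, seed=0)
        tt = TruthTrack(7, [0, 1], [[5000.0, 100.0]] * 2, 0, 1, 500.0)
        with pytest.raises(OutOfBoundsError) as err:
            render_frames([tt], cfg)
        assert err.value.track_ids == [7]

    def test_same_seed_renders_identical_frames(self):
        fx1 = default_fixture(seed=9, n_frames=20, n_bubbles=5)
        fx2 = default_fixture(seed=9, n_frames=20, n_bubbles=5)
        assert np.array_equal(fx1["movie"].frames, fx2["movie"].frames)


class TestHistologyCohort:
    def test_noiseless_truth_correlation_is_one(self):
        """True LVD and true vessel area are both affine in activation, so
        their sample correlation is exactly 1."""
        truth = draw_cohort_truth(SyntheticCohort(n=8, noise_sd=0.0, seed=0))
        lvd = [r["true_lvd_pct"] for r in truth]
        area = [r["true_vessel_area_px"] for r in truth]
        assert sps.pearsonr(lvd, area).statistic == pytest.approx(1.0, abs=1e-12)

    def test_zero_activation_hits_configured_floor(self):
        cohort = SyntheticCohort(n=2, activations=np.array([0.0, 1.0]), noise_sd=0.0, seed=0)
        pairs = simulate_histology_cohort(cohort)
        img, truth = pairs[0]
        assert truth["true_lvd_pct"] == pytest.approx(cohort.lvd_floor_pct)
        painted = 100.0 * (img.channels["LYVE1"] > 0).mean()
        # rasterized within one disk of the target (rasterization error)
        assert painted == pytest.approx(truth["true_lvd_pct"], abs=0.15)

    def test_latent_rho_mode_mean_r_in_fisher_band(self):
        """Monte-Carlo oracle: over replicate cohorts at latent ρ=0.9 the
        mean sample correlation falls inside the Fisher-z 95% interval."""
        rho, n = 0.9, 8
        rs = []
        for rep in range(500):
            truth = draw_cohort_truth(SyntheticCohort(n=n, rho=rho, seed=rep))
            lvd = [r["true_lvd_pct"] for r in truth]
            area = [r["true_vessel_area_px"] for r in truth]
            rs.append(sps.pearsonr(lvd, area).statistic)
        z = np.arctanh(rho)
        lo, hi = np.tanh(z - 1.96 / np.sqrt(n - 3)), np.tanh(z + 1.96 / np.sqrt(n - 3))
        assert lo < np.mean(rs) < hi

    def test_channels_share_shape_and_required_stains_present(self):
        pairs = simulate_histology_cohort(SyntheticCohort(n=2, seed=1))
        for img, _ in pairs:
            assert set(img.channels) == {"CD31", "LYVE1", "DAPI", "COL1"}
            assert len({v.shape for v in img.channels.values()}) == 1

    def test_cohort_of_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticCohort(n=1)


class TestDefaultFixture:
    def test_conservation_and_determinism(self, fx40):
        """Emitted truth tracks equal the requested bubble count, and the
        same seed reproduces the identical movie and tracks."""
        assert len(fx40["truth_tracks"]) == 40
        again = default_fixture(seed=42)
        assert np.array_equal(fx40["movie"].frames, again["movie"].frames)
        for a, b in zip(fx40["truth_tracks"], again["truth_tracks"]):
            assert np.array_equal(a.positions_um, b.positions_um)

    def test_tissue_casorati_matrix_is_rank_one(self, fx40):
        cfg = fx40["config"]
        tissue = render_frames([], cfg)
        casorati = tissue.frames.reshape(cfg.n_frames, -1).T
        s = np.linalg.svd(casorati, compute_uv=False)
        assert s[1] / s[0] < 1e-10
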