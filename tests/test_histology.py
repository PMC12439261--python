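"""Immunofluorescence binarization, lumen filling, channel subtraction and
density computation."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from lnulm.errors import InvalidRoiError, ShapeMismatchError
from lnulm.histology import (
    N_BINS,
    FluorescenceImage,
    binarize_channel,
    blood_lymph_split,
    compute_density,
    fill_lumina,
    otsu_threshold_scaled,
    quantify_node,
)
from lnulm.synthetic import SyntheticCohort, simulate_histology_cohort


def brute_force_otsu(channel):
    """Exhaustive search over all 256 histogram cuts maximizing the
    between-class variance (independent arithmetic)."""
    channel = np.asarray(channel, float)
    scaled = (channel - channel.min()) / (channel.max() - channel.min())
    hist, edges = np.histogram(scaled, bins=N_BINS, range=(0, 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    best_k, best_var = None, -1.0
    for k in range(N_BINS - 1):
        w0 = p[: k + 1].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (p[k + 1 :] * centers[k + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return edges[best_k + 1]


def annulus(shape, center, r_in, r_out):
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 <= r_out**2) & (d2 >= r_in**2)


class TestBinarize:
    def test_two_level_image_perfectly_separated(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((50, 50)) < 0.6, 200.0, 10.0)
        mask, log = binarize_channel(img, opening_radius=0)
        assert np.array_equal(mask, img == 200.0)
        assert 10.0 < log["threshold_intensity"] < 200.0

    def test_constant_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask, log = binarize_channel(np.full((10, 10), 7.0))
        assert not mask.any()
        assert log["threshold_scaled"] is None

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_threshold_equals_brute_force_search(self, seed):
        """The chosen cut attains the brute-force maximum between-class
        variance, and both cuts binarize the image identically (empty bins
        between the modes can tie at machine precision)."""
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(0.2, 0.05, 600), rng.normal(0.7, 0.1, 400)]
        ).reshape(40, 25)
        scaled = (img - img.min()) / (img.max() - img.min())

        def variance_at(thr):
            fg = scaled > thr
            w1 = fg.mean()
            if w1 in (0.0, 1.0):
                return -1.0
            return (1 - w1) * w1 * (scaled[~fg].mean() - scaled[fg].mean()) ** 2

        ours = otsu_threshold_scaled(img)
        brute = brute_force_otsu(img)
        assert variance_at(ours) == pytest.approx(variance_at(brute), rel=1e-9)
        assert np.array_equal(scaled > ours, scaled > brute)

    def test_threshold_close_to_skimage_reference(self):
        """Independent library cross-check: same histogram, thresholds agree
        to within one bin width."""
        rng = np.random.default_rng(4)
        img = np.concatenate([rng.normal(0.3, 0.05, 500), rng.normal(0.8, 0.05, 500)]).reshape(20, 50)
        scaled = (img - img.min()) / (img.max() - img.min())
        ours = otsu_threshold_scaled(img)
        ref = threshold_otsu(scaled, nbins=N_BINS)
        assert abs(ours - ref) <= 1.0 / N_BINS

    def test_opening_removes_isolated_pixels_and_is_idempotent(self):
        rng = np.random.default_rng(5)
        img = np.zeros((40, 40))
        img[10:20, 10:20] = 1.0
        img[2, 2] = 1.0  # isolated speck
        mask, _ = binarize_channel(img, opening_radius=1)
        assert not mask[2, 2]
        assert mask[12:18, 12:18].all()
        mask2, _ = binarize_channel(mask.astype(float) * 2, opening_radius=1)
        assert np.array_equal(mask, mask2)


class TestFillLumina:
    def test_annulus_becomes_filled_disk(self):
        ring = annulus((40, 40), (20, 20), 6, 10)
        filled, n = fill_lumina(ring)
        rr, cc = np.ogrid[0:40, 0:40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        assert n == 1
        assert np.array_equal(filled, disk | ring)

    def test_border_reaching_background_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5] = True
        mask[5:15, 14] = True
        mask[5, 5:15] = True  # open "U": interior reaches the border
        filled, n = fill_lumina(mask)
        assert n == 0
        assert np.array_equal(filled, mask)

    def test_nested_rings_match_border_flood_fill_oracle(self):
        outer = annulus((60, 60), (30, 30), 20, 24)
        inner = annulus((60, 60), (30, 30), 8, 12)
        mask = outer | inner
        filled, n = fill_lumina(mask)

        # oracle: 4-connected flood fill of background from the border
        from collections import deque

        reach = np.zeros_like(mask)
        q = deque()
        for r in range(60):
            for c in (0, 59):
                if not mask[r, c] and not reach[r, c]:
                    reach[r, c] = True
                    q.append((r, c))
        for c in range(60):
            for r in (0, 59):
                if not mask[r, c] and not reach[r, c]:
                    reach[r, c] = True
                    q.append((r, c))
        while q:
            r, c = q.popleft()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < 60 and 0 <= cc < 60 and not mask[rr, cc] and not reach[rr, cc]:
                    reach[rr, cc] = True
                    q.append((rr, cc))
        oracle = mask | ~reach
        assert np.array_equal(filled, oracle)
        assert n == 2

    def test_idempotent(self):
        mask = annulus((30, 30), (15, 15), 4, 8)
        once, _ = fill_lumina(mask)
        twice, n2 = fill_lumina(once)
        assert np.array_equal(once, twice)
        assert n2 == 0


class TestBloodLymphSplit:
    def test_overlap_subtracted(self):
        cd31 = np.zeros((20, 20), dtype=bool)
        cd31[0:10, 0:10] = True  # 100 px
        lyve1 = np.zeros((20, 20), dtype=bool)
        lyve1[7:10, 0:10] = True  # 30 px overlap
        blood, lymph = blood_lymph_split(cd31, lyve1)
        assert blood.sum() == 70
        assert np.array_equal(lymph, lyve1)

    def test_disjoint_masks_unchanged(self):
        cd31 = np.zeros((10, 10), dtype=bool)
        cd31[:3] = True
        lyve1 = np.zeros((10, 10), dtype=bool)
        lyve1[7:] = True
        blood, _ = blood_lymph_split(cd31, lyve1)
        assert np.array_equal(blood, cd31)

    def test_random_masks_match_boolean_oracle(self):
        rng = np.random.default_rng(6)
        cd31 = rng.random((30, 30)) > 0.5
        lyve1 = rng.random((30, 30)) > 0.7
        blood, lymph = blood_lymph_split(cd31, lyve1)
        for r in range(30):
            for c in range(30):
                assert blood[r, c] == (cd31[r, c] and not lyve1[r, c])
        assert not (blood & lymph).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            blood_lymph_split(np.zeros((5, 5), bool), np.zeros((6, 6), bool))


class TestDensity:
    def test_seventy_positive_in_thousand_roi(self):
        mask = np.zeros((40, 25), dtype=bool)
        mask.flat[:70] = True
        assert compute_density(mask, np.ones((40, 25), bool)) == pytest.approx(7.0)

    def test_mask_equal_roi_is_hundred_percent(self):
        roi = np.zeros((20, 20), dtype=bool)
        roi[5:15, 5:15] = True
        assert compute_density(roi, roi) == 100.0

    def test_filled_annulus_density_matches_analytic_disk_area(self):
        """After lumen filling, an annulus of outer radius R in an S×S ROI
        has density ~ 100·πR²/S² within 2% rasterization error."""
        shape, r_out = (200, 200), 40
        ring = annulus(shape, (100, 100), 25, r_out)
        filled, _ = fill_lumina(ring)
        density = compute_density(filled, np.ones(shape, bool))
        analytic = 100.0 * np.pi * r_out**2 / (200 * 200)
        assert density == pytest.approx(analytic, rel=0.02)

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidRoiError):
            compute_density(np.ones((5, 5), bool), np.zeros((5, 5), bool))


class TestQuantifyNode:
    def test_masks_disjoint_and_densities_bounded(self):
        pairs = simulate_histology_cohort(SyntheticCohort(n=3, seed=2))
        for img, _ in pairs:
            res = quantify_node(img)
            assert not (res.blood_mask & res.lymph_mask).any()
            assert 0 <= res.bvd_pct <= 100 and 0 <= res.lvd_pct <= 100
            assert res.bvd_pct + res.lvd_pct <= 100

    def test_measured_lvd_strictly_increasing_in_activation(self):
        """Cohort loop: on a noiseless cohort the measured lymphatic density
        increases monotonically with the latent activation."""
        cohort = SyntheticCohort(n=5, noise_sd=0.0, seed=3)
        pairs = simulate_histology_cohort(cohort)
        lvds = [quantify_node(img).lvd_pct for img, _ in pairs]
        acts = [truth["activation"] for _, truth in pairs]
        order = np.argsort(acts)
        lv = np.asarray(lvds)[order]
        assert np.all(np.diff(lv) > 0)

    def test_subtract_first_order_also_disjoint(self):
        pairs = simulate_histology_cohort(SyntheticCohort(n=2, seed=4))
        img, _ = pairs[0]
        res = quantify_node(img, subtract_first=True)
        assert not (res.blood_mask & res.lymph_mask).any()

    def test_missing_required_channel_rejected(self):
        from lnulm.errors import InvalidParameterError

        img = FluorescenceImage(channels={"CD31": np.zeros((5, 5))})
        with pytest.raises(InvalidParameterError):
            quantify_node(img)
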