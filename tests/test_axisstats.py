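"""Angle conventions, exact binomial test, binning, LRP6 localization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wntgrad import axisstats as ax
from wntgrad import synthdata as sd
from wntgrad.models import ResponseModel


class TestPoleAxisAngle:
    def test_toward_source_wall_is_zero(self):
        # bright pole displaced toward x = 0 (the Wnt-source wall)
        assert ax.pole_axis_angle((100.0, 500.0), (130.0, 500.0)) == \
            pytest.approx(0.0)

    def test_upstream_is_minus_half_pi(self):
        # bright pole displaced against the flow (smaller y)
        assert ax.pole_axis_angle((100.0, 400.0), (100.0, 430.0)) == \
            pytest.approx(-math.pi / 2)

    def test_swap_flips_by_pi(self):
        a = ax.pole_axis_angle((100.0, 400.0), (140.0, 470.0))
        b = ax.pole_axis_angle((140.0, 470.0), (100.0, 400.0))
        diff = (a - b) % (2 * math.pi)
        assert diff == pytest.approx(math.pi)

    def test_coincident_poles_raise(self):
        with pytest.raises(ValueError):
            ax.pole_axis_angle((1.0, 2.0), (1.0, 2.0))

    def test_range(self, rng):
        for _ in range(200):
            p, q = rng.uniform(0, 1000, (2, 2))
            t = ax.pole_axis_angle(p, q)
            assert -math.pi < t <= math.pi


class TestHalfPlaneClassification:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, True),
        (-math.pi / 2, True),     # boundary: included
        (math.pi / 2, False),     # boundary: excluded
        (math.pi, False),
        (-math.pi + 1e-9, False),
        (0.3, True),
    ])
    def test_toward_gradient_intervals(self, theta, expected):
        assert ax.classify_toward_gradient(theta) is expected

    @pytest.mark.parametrize("theta,expected", [
        (-math.pi / 2, True),
        (0.0, False),             # boundary: excluded
        (math.pi / 2, False),
        (-0.01, True),
        (math.pi, True),          # pi wraps to -pi, inside [-pi, 0)
    ])
    def test_toward_upstream_intervals(self, theta, expected):
        assert ax.classify_toward_upstream(theta) is expected

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-math.pi + 1e-9, math.pi))
    def test_antipodal_angles_disagree(self, theta):
        flipped = theta + math.pi
        assert ax.classify_toward_gradient(theta) != \
            ax.classify_toward_gradient(flipped)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-math.pi + 1e-6, math.pi - 1e-6))
    def test_wrap_invariance(self, theta):
        assert ax.classify_toward_gradient(theta) == \
            ax.classify_toward_gradient(theta + 2 * math.pi)


class TestExactBinomial:
    def test_reference_case(self):
        """39 of 56 toward the gradient: p = 0.0046 at printed precision."""
        p = ax.exact_binomial_two_sided(39, 56)
        assert round(p, 4) == 0.0046

    def test_symmetric_center_is_one(self):
        assert ax.exact_binomial_two_sided(28, 56) == 1.0

    def test_symmetry(self):
        for n in (5, 13, 56):
            for a in range(n + 1):
                assert ax.exact_binomial_two_sided(a, n) == \
                    ax.exact_binomial_two_sided(n - a, n)

    def test_matches_enumeration_oracle(self):
        """Exhaustive enumeration over outcome probabilities, n <= 20."""
        for n in range(1, 21):
            pmf = [math.comb(n, k) * 0.5 ** n for k in range(n + 1)]
            for a in range(n + 1):
                oracle = sum(p for p in pmf if p <= pmf[a] * (1 + 1e-9))
                assert abs(ax.exact_binomial_two_sided(a, n)
                           - min(oracle, 1.0)) < 1e-12

    def test_matches_scipy(self):
        """Independent library cross-check on assorted cases."""
        from scipy.stats import binomtest
        for a, n, p0 in [(39, 56, 0.5), (3, 10, 0.5), (45, 100, 0.5),
                         (7, 20, 0.3), (12, 15, 0.7)]:
            assert ax.exact_binomial_two_sided(a, n, p0) == pytest.approx(
                binomtest(a, n, p0).pvalue, abs=1e-12)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            ax.exact_binomial_two_sided(5, 4)
        with pytest.raises(ValueError):
            ax.exact_binomial_two_sided(-1, 4)


class TestEqualCountBins:
    def test_forty_cells_four_bins(self, rng):
        bins = ax.equal_count_bins(rng.random(40), k=4)
        assert bins.counts == [10, 10, 10, 10]

    def test_remainder_to_lowest_bins(self, rng):
        bins = ax.equal_count_bins(rng.random(10), k=4)
        assert bins.counts == [3, 3, 2, 2]

    def test_all_equal_flagged_degenerate(self):
        bins = ax.equal_count_bins(np.ones(8), k=4)
        assert bins.degenerate
        assert all(e == 1.0 for e in bins.edges)

    def test_every_value_binned_once(self, rng):
        v = rng.random(37)
        bins = ax.equal_count_bins(v, k=4)
        assert np.bincount(bins.assignments, minlength=4).tolist() == \
            bins.counts

    def test_edges_bracket_sorted_groups(self, rng):
        v = rng.random(100)
        bins = ax.equal_count_bins(v, k=4)
        for i in range(4):
            grp = v[bins.assignments == i]
            assert grp.min() >= bins.edges[i] - 1e-12
            assert grp.max() <= bins.edges[i + 1] + 1e-12

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            ax.equal_count_bins(np.arange(3.0), k=4)


class TestSensitivityThreshold:
    @staticmethod
    def _bins_with(p_values, fractions):
        from wntgrad.models import OrientationTest, SensitivityBins
        bins = SensitivityBins(k=4, edges=[0.0, 1.0, 2.0, 3.0, 4.0],
                               counts=[10] * 4)
        bins.tests = [
            OrientationTest(a=int(round(f * 10)), b=10 - int(round(f * 10)),
                            p_value=p)
            for p, f in zip(p_values, fractions)]
        return bins

    def test_no_significant_bin_undefined(self):
        bins = self._bins_with([0.4, 0.8, 0.2, 0.6], [0.6, 0.5, 0.6, 0.6])
        assert ax.sensitivity_threshold(bins).threshold_nM_per_um is None

    def test_top_bin_significant_gives_its_lower_edge(self):
        bins = self._bins_with([0.9, 0.7, 0.3, 0.01], [0.5, 0.5, 0.6, 0.8])
        out = ax.sensitivity_threshold(bins)
        assert out.threshold_nM_per_um == 3.0
        assert out.threshold_bin == 3

    def test_significant_against_bias_ignored(self):
        # significant but toward-fraction < 0.5 must not define a threshold
        bins = self._bins_with([0.01, 0.9, 0.9, 0.9], [0.1, 0.5, 0.5, 0.5])
        assert ax.sensitivity_threshold(bins).threshold_nM_per_um is None

    def test_planted_threshold_recovered(self, geometry, flow):
        """Cohorts with a planted step threshold localize it to within one
        bin width in most seeded runs."""
        fit = sd.default_device_fit()
        resp = ResponseModel()  # planted threshold 1.0e-3 nM/um
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            cells = sd.generate_cell_population(400, geometry, fit, resp,
                                                seed=seed, flow=flow)
            bins = ax.bin_orientation_tests(
                np.abs(cells.delta_c_nM_per_um.to_numpy()),
                cells.theta_rad.to_numpy(), k=4)
            bins = ax.sensitivity_threshold(bins)
            if bins.threshold_bin is not None:
                width = (bins.edges[bins.threshold_bin + 1]
                         - bins.edges[bins.threshold_bin])
                hits += abs(bins.threshold_nM_per_um
                            - resp.threshold_nM_per_um) <= width
        assert hits / n_runs >= 0.8


class TestRoseHistogram:
    def test_counts_conserved(self, rng):
        t = rng.uniform(-math.pi, math.pi, 571)
        assert ax.rose_histogram(t).sum() == 571

    def test_all_zero_angles_single_sector(self):
        counts = ax.rose_histogram(np.zeros(50))
        assert counts.max() == 50
        assert (counts > 0).sum() == 1
        # the sector containing 0 starts at 0 (left-closed convention)
        assert np.argmax(counts) == 6

    def test_uniform_fill(self, rng):
        counts = ax.rose_histogram(rng.uniform(-math.pi, math.pi, 1200), 12)
        # multinomial: each sector 100 +- 3 sd
        sd_ = math.sqrt(1200 * (1 / 12) * (11 / 12))
        assert np.all(np.abs(counts - 100) <= 3 * sd_)

    def test_pi_wraps_to_first_sector(self):
        assert ax.rose_histogram(np.array([math.pi]))[0] == 1


class TestCellCenter:
    def test_single_blob_geometric_center(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[8:13, 6:11] = True
        assert ax.cell_center([mask], "metaphase") == (10.0, 8.0)

    def test_two_blob_midpoint(self):
        m1 = np.zeros((30, 30), dtype=bool)
        m2 = np.zeros((30, 30), dtype=bool)
        m1[0, 0] = True
        m2[10, 0] = True
        assert ax.cell_center([m1, m2], "postmetaphase") == (5.0, 0.0)

    def test_wrong_mask_count_raises(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            ax.cell_center([m, m], "metaphase")
        with pytest.raises(ValueError):
            ax.cell_center([m], "postmetaphase")

    def test_center_recovery_on_synthetic_images(self, geometry):
        """Within 2 px of the planted centre across seeds and phases."""
        errs = []
        for seed in range(60):
            phase = "metaphase" if seed % 2 else "postmetaphase"
            img, truth = sd.generate_lrp6_image((48, 48), "toward", geometry,
                                                seed=seed, phase=phase, snr=5)
            masks = ax.segment_chromosomes(img[0], phase)
            center = ax.cell_center(masks, phase, intensity=img[0])
            errs.append(np.hypot(center[0] - truth.center[0],
                                 center[1] - truth.center[1]))
        assert np.max(errs) < 2.0


class TestLrp6Window:
    def test_bright_spot_centers_window(self):
        # a symmetric spot makes the centred placement the unique maximum
        yy, xx = np.mgrid[0:30, 0:30]
        img = np.exp(-((yy - 17) ** 2 + (xx - 12) ** 2) / 8.0)
        assert ax.lrp6_activated_position(img, 11) == (17, 12)

    def test_uniform_image_first_placement(self):
        assert ax.lrp6_activated_position(np.ones((20, 20)), 11) == (5, 5)

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            ax.lrp6_activated_position(np.ones((20, 20)), 10)

    def test_matches_brute_force(self, rng):
        """Integral-image scan equals exhaustive all-placements search."""
        for _ in range(50):
            img = rng.random((rng.integers(15, 40), rng.integers(15, 40)))
            w = 11
            best, best_val = None, -np.inf
            for r in range(img.shape[0] - w + 1):
                for c in range(img.shape[1] - w + 1):
                    v = img[r:r + w, c:c + w].sum()
                    if v > best_val:
                        best, best_val = (r + w // 2, c + w // 2), v
            assert ax.lrp6_activated_position(img, w) == best


class TestLrp6Side:
    def test_toward_wall_displacement(self):
        assert ax.classify_lrp6_side((50, 30), (50, 40)) == "toward"
        assert ax.classify_lrp6_side((50, 45), (50, 40)) == "against"

    def test_pure_flow_displacement_indeterminate(self):
        assert ax.classify_lrp6_side((60, 40), (50, 40)) == "indeterminate"

    def test_upstream_reference(self):
        assert ax.classify_lrp6_side((40, 40), (50, 40),
                                     reference="upstream") == "toward"

    def test_coincident_raises(self):
        with pytest.raises(ValueError):
            ax.classify_lrp6_side((5, 5), (5, 5))

    def test_side_recovery_at_snr5(self, geometry):
        """>= 95% correct side calls over seeded synthetic cells."""
        ok = 0
        n = 100
        for seed in range(n):
            side = "toward" if seed % 2 else "against"
            phase = "metaphase" if seed % 3 else "postmetaphase"
            img, truth = sd.generate_lrp6_image((48, 48), side, geometry,
                                                seed=seed, phase=phase, snr=5)
            masks = ax.segment_chromosomes(img[0], phase)
            center = ax.cell_center(masks, phase, intensity=img[0])
            act = ax.lrp6_activated_position(img[1])
            ok += ax.classify_lrp6_side(act, center) == truth.true_side
        assert ok / n >= 0.95


class TestOrientationTestHelper:
    def test_counts_and_probability(self):
        thetas = [0.0] * 39 + [math.pi] * 17
        t = ax.orientation_test(thetas)
        assert (t.a, t.b) == (39, 17)
        assert t.fraction_toward == pytest.approx(39 / 56)
        assert round(t.p_value, 4) == 0.0046

    def test_null_type_one_error_calibrated(self, geometry, flow):
        """Unbiased cohorts reject at ~alpha (binomial band over runs)."""
        fit = sd.default_device_fit()
        resp = ResponseModel(threshold_nM_per_um=np.inf)
        rejections = 0
        n_runs = 60
        for seed in range(n_runs):
            cells = sd.generate_cell_population(200, geometry, fit, resp,
                                                seed=seed, flow=flow)
            t = ax.orientation_test(cells.theta_rad.to_numpy())
            rejections += t.p_value < 0.05
        band = 3 * math.sqrt(0.05 * 0.95 / n_runs)
        assert abs(rejections / n_runs - 0.05) <= band + 0.01
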