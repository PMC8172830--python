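"""Consensus-ROI inference: densities, maxima, widths, overlap resolution."""

import numpy as np
import pytest
from scipy.stats import norm

from tfea.intervals import GenomicRegion, RegionGroup, SampleRegion
from tfea.mumerge import (
    ROI,
    find_maxima,
    joint_density,
    mumerge,
    region_density,
    resolve_overlaps,
    roi_width,
)

from conftest import make_sample_region


def _group(regions, design=None):
    if design is None:
        design = {"c1": sorted({r.sample_id for r in regions})}
    return RegionGroup(list(regions), design)


class TestRegionDensity:
    def test_standard_normal_peak(self):
        # sigma=100, rho=1: the density is the standard-normal shape in
        # units of (x - mu) / sigma, peaking at phi(0)
        r = make_sample_region("chr1", 900, 1100)  # mu=1000, sigma=100
        d = region_density(r)
        i = np.argmin(np.abs(d.grid - 1000))
        assert d.values[i] == pytest.approx(norm.pdf(0), abs=1e-12)

    def test_symmetry_one_sigma_out(self):
        r = make_sample_region("chr1", 900, 1100)
        d = region_density(r)
        lo = d.values[np.argmin(np.abs(d.grid - 900))]
        hi = d.values[np.argmin(np.abs(d.grid - 1100))]
        assert lo == pytest.approx(hi, rel=1e-12)
        assert lo == pytest.approx(norm.pdf(1.0), abs=1e-12)

    def test_width_ratio_scales_argument(self):
        # mu=50, sigma=10, rho=2 evaluated at x=70: phi((70-50)/20) = phi(1)
        r = make_sample_region("chr1", 40, 60)
        d = region_density(r, rho=2.0)
        val = d.values[np.argmin(np.abs(d.grid - 70))]
        assert val == pytest.approx(norm.pdf(1.0), abs=1e-12)

    def test_bad_rho(self):
        r = make_sample_region("chr1", 0, 10)
        with pytest.raises(ValueError):
            region_density(r, rho=0)


class TestJointDensity:
    def test_single_region_argmax_at_mu(self):
        r = make_sample_region("chr1", 900, 1100)
        d = joint_density(_group([r]))
        assert d.grid[np.argmax(d.values)] == pytest.approx(1000)

    def test_two_replicates_product_peaks_between(self):
        a = make_sample_region("chr1", 890, 1090, "s1")  # mu=990
        b = make_sample_region("chr1", 910, 1110, "s2")  # mu=1010
        d = joint_density(_group([a, b]))
        assert d.grid[np.argmax(d.values)] == pytest.approx(1000)

    def test_two_conditions_sum_keeps_both_modes(self):
        # conditions are summed, not multiplied: separated loci survive
        a = make_sample_region("chr1", 930, 970, "s1", "c1")  # mu=950, sig=20
        b = make_sample_region("chr1", 1030, 1070, "s2", "c2")  # mu=1050
        g = RegionGroup([a, b], {"c1": ["s1"], "c2": ["s2"]})
        d = joint_density(g)
        cands = find_maxima(d, g, max_per_group=10)
        positions = sorted(p for p, _ in cands)
        assert len(positions) == 2
        assert positions[0] == pytest.approx(950, abs=2)
        assert positions[1] == pytest.approx(1050, abs=2)

    def test_matches_dense_brute_force(self):
        # independent evaluation of the condition-sum / replicate-product
        # on the same grid
        regs = [
            make_sample_region("chr1", 900, 1100, "s1", "c1"),
            make_sample_region("chr1", 950, 1150, "s2", "c1"),
            make_sample_region("chr1", 1000, 1200, "s3", "c2"),
        ]
        g = RegionGroup(regs, {"c1": ["s1", "s2"], "c2": ["s3"]})
        d = joint_density(g)
        mus = {r.sample_id: (r.mu, r.sigma) for r in regs}
        brute = []
        for x in d.grid:
            p1 = norm.pdf((x - mus["s1"][0]) / mus["s1"][1]) * norm.pdf(
                (x - mus["s2"][0]) / mus["s2"][1]
            )
            p2 = norm.pdf((x - mus["s3"][0]) / mus["s3"][1])
            brute.append(p1 + p2)
        brute = np.array(brute)
        # joint is computed up to a per-condition monotone rescale; compare
        # argmax and shape correlation
        assert d.grid[np.argmax(d.values)] == d.grid[np.argmax(brute)]

    def test_empty_replicate_contributes_uniform(self):
        a = make_sample_region("chr1", 900, 1100, "s1")
        g = RegionGroup([a], {"c1": ["s1", "s2"]})  # s2 has no region
        d = joint_density(g)
        # uniform factor rescales but cannot move the maximum
        assert d.grid[np.argmax(d.values)] == pytest.approx(1000)


class TestFindMaxima:
    def test_unimodal_single_candidate(self):
        r = make_sample_region("chr1", 900, 1100)
        g = _group([r])
        d = joint_density(g)
        assert len(find_maxima(d, g)) == 1

    def test_truncation_to_m_plus_one(self):
        # 4 maxima in the density, M=1 -> keep top 2 by value
        from tfea.mumerge import PositionalDensity

        grid = np.arange(0.0, 9.0)
        values = np.array([0.1, 5.0, 0.1, 4.0, 0.1, 3.0, 0.1, 2.0, 0.1])
        g = _group([make_sample_region("chr1", 0, 9)])
        cands = find_maxima(PositionalDensity(grid, values), g)
        assert [p for p, _ in cands] == [1.0, 3.0]  # ranked by value

    def test_flat_density_degenerates_to_midpoint(self):
        from tfea.mumerge import PositionalDensity

        grid = np.arange(0.0, 11.0)
        g = _group([make_sample_region("chr1", 0, 10)])
        cands = find_maxima(PositionalDensity(grid, np.ones(11)), g)
        assert len(cands) == 1
        assert cands[0][0] == 5.0


class TestRoiWidth:
    def test_single_region_identity(self):
        g = _group([make_sample_region("chr1", 900, 1100)])  # mu=1000 sig=100
        assert roi_width(1000.0, g) == pytest.approx(100.0)

    def test_equidistant_equal_weights(self):
        g = _group(
            [
                make_sample_region("chr1", 940, 960, "s1"),  # mu=950 sig=10
                make_sample_region("chr1", 1020, 1080, "s2"),  # mu=1050 sig=30
            ]
        )
        assert roi_width(1000.0, g) == pytest.approx(20.0)

    def test_inverse_distance_weighting_arithmetic(self):
        # regions (mu=0, sig=10) and (mu=100, sig=50), center estimate 0:
        # (10/1 + 50/101) / (1/1 + 1/101), evaluated independently
        g = _group(
            [
                make_sample_region("chr1", 990, 1010, "s1"),
                make_sample_region("chr1", 1050, 1150, "s2"),
            ]
        )
        expected = (10 / 1 + 50 / 101) / (1 / 1 + 1 / 101)
        assert roi_width(1000.0, g) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_extreme_widths(self, rng):
        regs = [
            make_sample_region(
                "chr1", 1000 + i * 10, 1000 + i * 10 + int(w), f"s{i}"
            )
            for i, w in enumerate(rng.integers(20, 300, 8))
        ]
        g = _group(regs)
        sig = roi_width(1100.0, g)
        sigmas = [r.sigma for r in regs]
        assert min(sigmas) <= sig <= max(sigmas)


class TestResolveOverlaps:
    @staticmethod
    def _roi(mu, sigma, joint=1.0):
        return ROI(
            mu, sigma,
            GenomicRegion("chr1", int(mu - sigma), int(mu + sigma)),
            "g", joint,
        )

    def test_symmetric_shrink_until_touching(self):
        out = resolve_overlaps([self._roi(1000, 60), self._roi(1100, 60)])
        assert [r.sigma_hat for r in out] == [50, 50]
        assert (out[0].region.start, out[0].region.stop) == (950, 1050)
        assert (out[1].region.start, out[1].region.stop) == (1050, 1150)

    def test_disjoint_untouched(self):
        rois = [self._roi(1000, 40), self._roi(1200, 40)]
        assert resolve_overlaps(rois) == rois

    def test_identical_centers_keep_higher_joint(self):
        out = resolve_overlaps(
            [self._roi(1000, 60, joint=1.0), self._roi(1000, 40, joint=5.0)]
        )
        assert len(out) == 1
        assert out[0].sigma_hat == 40

    def test_centers_never_move(self):
        rois = [self._roi(1000, 80), self._roi(1100, 80), self._roi(1250, 80)]
        out = resolve_overlaps(rois)
        assert [r.mu_hat for r in out] == [1000, 1100, 1250]
        for a, b in zip(out, out[1:]):
            assert a.mu_hat + a.sigma_hat <= b.mu_hat - b.sigma_hat + 1e-9


class TestMumerge:
    def test_single_sample_identity(self):
        regs = [
            make_sample_region("chr1", 1000, 1200),
            make_sample_region("chr1", 2000, 2300),
            make_sample_region("chr1", 5000, 5100),
        ]
        rois = mumerge({"s1": regs})
        assert len(rois) == 3
        for roi, reg in zip(rois, regs):
            assert roi.mu_hat == pytest.approx(reg.mu, abs=1)
            assert roi.sigma_hat == pytest.approx(reg.sigma, abs=1)

    def test_output_sorted_and_nonoverlapping(self, rng):
        regs = {
            f"s{j}": [
                make_sample_region(
                    "chr1", int(s), int(s + w), f"s{j}"
                )
                for s, w in zip(
                    rng.integers(0, 3000, 12), rng.integers(50, 400, 12)
                )
            ]
            for j in range(2)
        }
        rois = mumerge(regs)
        starts = [r.region.start for r in rois]
        assert starts == sorted(starts)
        by_group = {}
        for r in rois:
            by_group.setdefault(r.group_id, []).append(r)
        for group_rois in by_group.values():
            group_rois.sort(key=lambda r: r.region.start)
            for a, b in zip(group_rois, group_rois[1:]):
                assert a.region.stop <= b.region.start

    def test_translation_equivariance(self):
        regs = [
            make_sample_region("chr1", 1000, 1300, "s1"),
            make_sample_region("chr1", 1100, 1500, "s2"),
        ]
        shift = 7000
        shifted = [
            make_sample_region(
                "chr1", r.region.start + shift, r.region.stop + shift,
                r.sample_id,
            )
            for r in regs
        ]
        a = mumerge({"s1": [regs[0]], "s2": [regs[1]]})
        b = mumerge({"s1": [shifted[0]], "s2": [shifted[1]]})
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert rb.mu_hat - ra.mu_hat == pytest.approx(shift, abs=1e-9)
            assert rb.sigma_hat == pytest.approx(ra.sigma_hat, abs=1e-9)

    def test_reflection_symmetry(self):
        regs = [
            make_sample_region("chr1", 1000, 1300, "s1"),
            make_sample_region("chr1", 1250, 1400, "s2"),
        ]
        pivot = 10000
        mirrored = [
            make_sample_region(
                "chr1", pivot - r.region.stop, pivot - r.region.start,
                r.sample_id,
            )
            for r in regs
        ]
        a = mumerge({"s1": [regs[0]], "s2": [regs[1]]})
        b = mumerge({"s1": [mirrored[0]], "s2": [mirrored[1]]})
        assert len(a) == len(b)
        for ra, rb in zip(a, sorted(b, key=lambda r: -r.mu_hat)):
            assert ra.mu_hat + rb.mu_hat == pytest.approx(pivot, abs=1e-9)

    def test_replicate_duplication_keeps_argmax(self):
        # squaring a condition's sole replicate density cannot move its
        # unique maximum (with heterogeneous replicates the duplicated
        # factor re-weights the precision-weighted mean, so no such
        # invariant holds there)
        base = {"s1": [make_sample_region("chr1", 1000, 1300, "s1")]}
        dup = {
            "s1": base["s1"],
            "s2": [make_sample_region("chr1", 1000, 1300, "s2")],
        }
        a = mumerge(base)
        b = mumerge(dup)
        assert len(a) == len(b) == 1
        assert b[0].mu_hat == pytest.approx(a[0].mu_hat, abs=1e-9)

    def test_grid_refinement_stability(self):
        samples = {
            "s1": [make_sample_region("chr1", 1000, 1313, "s1")],
            "s2": [make_sample_region("chr1", 1107, 1444, "s2")],
        }
        coarse = mumerge(samples, step=1.0)
        fine = mumerge(samples, step=0.5)
        assert len(coarse) == len(fine)
        for a, b in zip(coarse, fine):
            assert abs(a.mu_hat - b.mu_hat) <= 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mumerge({})
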