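"""Unbiased frames: placement, edge-rule counting, N_A and the Cochran CE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nihlsim.cochlea import SamplingSubstrate
from nihlsim.stereology import (CountingFrame, SamplingDesign,
                                UndefinedDensityError, coefficient_of_error,
                                count_frame, density, estimate_sector,
                                place_frames, sampled_area)


def make_substrate(points=(), classes=(), length=256.5, width=28.0, label=25.0):
    return SamplingSubstrate(label, length, width,
                             np.array(points, float).reshape(-1, 2),
                             np.array(classes, object))


class TestPlaceFrames:
    def test_systematic_period_and_no_overlap(self):
        sub = make_substrate()
        frames = place_frames(sub, SamplingDesign(seed=4))
        x0 = np.array([f.x0 for f in frames])
        assert len(frames) == 5
        assert np.allclose(np.diff(x0), 256.5 / 5)      # fixed period 51.3 µm
        assert np.all(np.diff(x0) >= 25.0)              # non-overlapping
        assert x0[0] >= 0 and x0[-1] + 25.0 <= 256.5

    def test_same_seed_same_placement(self):
        sub = make_substrate()
        a = place_frames(sub, SamplingDesign(seed=11))
        b = place_frames(sub, SamplingDesign(seed=11))
        assert [(f.x0, f.y0) for f in a] == [(f.x0, f.y0) for f in b]

    def test_sector_too_short_rejected(self):
        sub = make_substrate()
        with pytest.raises(ValueError, match="non-overlapping"):
            place_frames(sub, SamplingDesign(frames_per_sector=11))  # 11·25 > 256.5

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SamplingDesign(frames_per_sector=1)
        with pytest.raises(ValueError):
            SamplingDesign(frame_width_um=0)
        with pytest.raises(ValueError):
            SamplingDesign(lateral_placement="nope")


class TestCountFrame:
    def frame(self, x0=100.0, y0=1.0):
        return CountingFrame(x0=x0, y0=y0, width=25.0, height=25.0)

    def test_empty_region_counts_zero(self):
        sub = make_substrate()
        f = count_frame(self.frame(), sub)
        assert f.counts == {"IHC": 0, "OHC": 0}

    def test_inclusion_exclusion_edges(self):
        # exclusion edges (left x0, bottom y0) lose the point; inclusion
        # edges (right, top) keep it
        f = self.frame()
        pts = [(100.0, 10.0),   # on left edge -> excluded
               (110.0, 1.0),    # on bottom edge -> excluded
               (125.0, 10.0),   # on right edge -> included
               (110.0, 26.0),   # on top edge -> included
               (110.0, 10.0)]   # interior -> included
        sub = make_substrate(pts, ["OHC"] * 5)
        assert count_frame(f, sub).counts["OHC"] == 3

    def test_classes_counted_separately(self):
        sub = make_substrate([(110, 10), (111, 10), (112, 12)],
                             ["OHC", "IHC", "OHC"])
        f = count_frame(self.frame(), sub)
        assert f.counts == {"IHC": 1, "OHC": 2}

    def test_lateral_wrap_counts_across_fringe_edge(self):
        # frame starting at y0=20 on a 28 µm torus reaches y ∈ (20,28]∪(0,17]
        f = CountingFrame(x0=100.0, y0=20.0, width=25.0, height=25.0,
                          wrap_width=28.0)
        sub = make_substrate([(110, 2.0), (110, 19.0), (110, 24.0)],
                             ["OHC"] * 3)
        assert count_frame(f, sub).counts["OHC"] == 2  # y=19 in the 3 µm gap

    def test_agreement_with_brute_force_oracle(self, rng):
        pts = np.column_stack([rng.uniform(0, 256.5, 300),
                               rng.uniform(0, 28.0, 300)])
        sub = make_substrate(pts, ["OHC"] * 300)

        def oracle(fr):
            n = 0
            for x, y in pts:
                dx = x - fr.x0
                dy = (y - fr.y0) % 28.0 if fr.wrap_width else y - fr.y0
                if 0 < dx <= fr.width and 0 < dy <= fr.height:
                    n += 1
            return n

        for _ in range(100):
            fr = CountingFrame(x0=rng.uniform(0, 230), y0=rng.uniform(0, 28),
                               width=25.0, height=25.0, wrap_width=28.0)
            assert count_frame(fr, sub).counts["OHC"] == oracle(fr)


class TestSampledArea:
    def test_all_corners_inside(self):
        sub = make_substrate()
        frames = place_frames(sub, SamplingDesign(seed=0))
        for f in frames:
            count_frame(f, sub)
        assert sampled_area(frames) == pytest.approx(5 * 625.0)

    def test_partial_corner_hits(self):
        # frame sticking out of the fringe top: only its 2 bottom corners hit
        sub = make_substrate()
        f = CountingFrame(x0=10.0, y0=10.0, width=25.0, height=25.0)
        count_frame(f, sub)
        assert f.corner_hits == 2
        assert sampled_area([f]) == pytest.approx(312.5)

    def test_no_hits_gives_zero_area(self):
        sub = make_substrate()
        f = CountingFrame(x0=10.0, y0=50.0, width=25.0, height=25.0)
        count_frame(f, sub)
        assert f.corner_hits == 0
        assert sampled_area([f]) == 0.0


class TestDensity:
    def test_printed_formula_arithmetic(self):
        assert density(31, 3125.0) == pytest.approx(9.92)
        assert density(0, 3125.0) == 0.0

    def test_zero_area_is_an_explicit_error(self):
        with pytest.raises(UndefinedDensityError):
            density(5, 0.0)


class TestCoefficientOfError:
    def test_constant_ratio_gives_zero(self):
        assert coefficient_of_error([7, 7, 7], [625] * 3) == pytest.approx(0.0)
        # q proportional to a is also exact
        assert coefficient_of_error([2, 4, 6], [100, 200, 300]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_worked_frame_set(self):
        # q=(6,7,8,7,9), a=625 each: CE = sqrt(279/1369 - 1/5) ≈ 0.0617
        ce = coefficient_of_error([6, 7, 8, 7, 9], [625.0] * 5)
        assert ce == pytest.approx(np.sqrt(279 / 1369 - 0.2), rel=1e-9)
        assert ce == pytest.approx(0.0617, abs=0.0005)

    def test_zero_counts_flagged_nan(self):
        assert np.isnan(coefficient_of_error([0, 0, 0], [625.0] * 3))

    def test_poisson_ce_matches_inverse_sqrt_nm(self, rng):
        # constant area, Poisson counts: E[CE] -> 1/sqrt(n·m) for large n
        n, m, reps = 50, 20.0, 2000
        ces = []
        for _ in range(reps):
            q = rng.poisson(m, n)
            ces.append(coefficient_of_error(q, np.full(n, 625.0)))
        assert np.mean(ces) == pytest.approx(1 / np.sqrt(n * m), rel=0.05)

    def test_bessel_correction_factor(self):
        q, a = [6, 7, 8, 7, 9], [625.0] * 5
        plain = coefficient_of_error(q, a)
        corrected = coefficient_of_error(q, a, bessel=True)
        assert corrected == pytest.approx(plain * np.sqrt(5 / 4), rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=12),
           st.lists(st.floats(1.0, 1000.0), min_size=12, max_size=12))
    def test_ce_is_nonnegative_and_finite(self, q, a):
        ce = coefficient_of_error(q, a[:len(q)])
        if sum(q) > 0:
            assert ce >= 0 and np.isfinite(ce)


class TestEstimateSector:
    def test_zero_bundle_substrate(self):
        sub = make_substrate()
        for est in estimate_sector(sub, SamplingDesign(seed=2)):
            assert est.n_a_per_1000um2 == 0.0
            assert np.isnan(est.ce)

    def test_recovers_control_density_in_expectation(self, control_map):
        # OHC expectation 11.905/1000µm² (fringe-average, toroidal sampling)
        from nihlsim import render_sector_substrate
        vals = []
        rng = np.random.default_rng(77)
        for seed in range(40):
            for label in (20, 40, 60):
                sub = render_sector_substrate(control_map, label)
                est = {e.cell_class: e for e in
                       estimate_sector(sub, SamplingDesign(), rng=rng)}
                vals.append(est["OHC"].n_a_per_1000um2)
        assert np.mean(vals) == pytest.approx(
            control_map.true_density("OHC"), rel=0.05)

    def test_doubling_frames_shrinks_ce_by_sqrt2(self):
        # asymptotic 1/sqrt(n) scaling, tested on long strips with enough
        # frames that the small-sample bias of the CE statistic is negligible
        rng = np.random.default_rng(5)
        L, W, dens = 2565.0, 28.0, 3 / (9.0 * 28.0)  # OHC-like surface density
        means = {}
        for n in (25, 50):
            ces = []
            for _ in range(150):
                npts = rng.poisson(dens * L * W)
                pts = np.column_stack([rng.uniform(0, L, npts),
                                       rng.uniform(0, W, npts)])
                sub = make_substrate(pts, ["OHC"] * npts, length=L, width=W)
                ests = estimate_sector(
                    sub, SamplingDesign(frames_per_sector=n), rng=rng)
                ces.append([e for e in ests if e.cell_class == "OHC"][0].ce)
            means[n] = np.nanmean(ces)
        assert means[50] / means[25] == pytest.approx(1 / np.sqrt(2), rel=0.07)

    def test_shared_area_between_classes(self, control_map):
        from nihlsim import render_sector_substrate
        sub = render_sector_substrate(control_map, 40)
        ihc, ohc = {}, {}
        ests = estimate_sector(sub, SamplingDesign(seed=8))
        areas = {e.cell_class: e.sum_a_um2 for e in ests}
        assert areas["IHC"] == areas["OHC"]
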