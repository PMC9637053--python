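import numpy as np
import pytest

from fatmap.core import (
    NormalizedProfile,
    RadialProfile,
    build_radial_profile,
    detect_peak,
    normalize_profile,
    overall_mean_fi,
    peak_prevalence,
    read_profiles_csv,
    smooth_profile,
    write_profiles_csv,
)
from fatmap.geometry import CenterOfRotation, distance_map
from fatmap.io import FatFractionSlice, MuscleMask


def _profile(mean_fi, **kw):
    mean_fi = np.asarray(mean_fi, float)
    counts = np.where(np.isfinite(mean_fi), 1, 0)
    kw.setdefault("muscle", "multifidus")
    kw.setdefault("cor", CenterOfRotation((0.0, 0.0)))
    return RadialProfile(mean_fi=mean_fi, pixel_count=counts, **kw)


def _normalized(fi, **kw):
    fi = np.asarray(fi, float)
    kw.setdefault("muscle", "multifidus")
    return NormalizedProfile(nodes=np.linspace(0, 100, fi.size), fi=fi, **kw)


class TestBuildRadialProfile:
    def test_constant_field_gives_constant_annuli(self, cor_center):
        fi = FatFractionSlice(np.full((15, 15), 37.0))
        mask = MuscleMask(np.ones((15, 15), bool), muscle="multifidus")
        p = build_radial_profile(fi, mask, cor_center)
        assert np.allclose(p.mean_fi[p.occupied], 37.0)

    def test_single_pixel_lands_in_floor_annulus(self):
        values = np.zeros((6, 6))
        values[0, 0] = 40.0
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True
        cor = CenterOfRotation((0.0, 2.5))  # pixel (0,0) at distance 2.5
        p = build_radial_profile(
            FatFractionSlice(values), MuscleMask(mask, muscle="psoas"), cor
        )
        assert p.mean_fi[2] == pytest.approx(40.0)
        assert np.isnan(p.mean_fi[:2]).all()
        assert p.pixel_count[2] == 1

    def test_matches_brute_force_binning(self, random_slice_and_mask, cor_center):
        """Per-annulus means equal an explicit per-pixel loop."""
        fi, mask = random_slice_and_mask
        p = build_radial_profile(fi, mask, cor_center)
        d = distance_map(fi.shape, cor_center)
        groups: dict[int, list[float]] = {}
        for r in range(15):
            for c in range(15):
                if mask.mask[r, c]:
                    groups.setdefault(int(np.floor(d[r, c])), []).append(fi.values[r, c])
        for k in range(p.n_annuli):
            if k in groups:
                assert p.mean_fi[k] == pytest.approx(np.mean(groups[k]), abs=1e-12)
                assert p.pixel_count[k] == len(groups[k])
            else:
                assert np.isnan(p.mean_fi[k])

    def test_partition_of_mask_pixels(self, random_slice_and_mask, cor_center):
        fi, mask = random_slice_and_mask
        p = build_radial_profile(fi, mask, cor_center)
        assert p.pixel_count.sum() == mask.n_pixels

    def test_missing_pixels_excluded(self, cor_center):
        values = np.full((15, 15), 30.0)
        values[7, 7] = np.nan
        mask = np.ones((15, 15), bool)
        p = build_radial_profile(
            FatFractionSlice(values), MuscleMask(mask, muscle="multifidus"), cor_center
        )
        assert p.pixel_count.sum() == mask.sum() - 1
        assert np.allclose(p.mean_fi[p.occupied], 30.0)

    def test_empty_mask_rejected(self, cor_center):
        fi = FatFractionSlice(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty mask"):
            build_radial_profile(fi, MuscleMask(np.zeros((4, 4), bool), muscle="psoas"), cor_center)

    def test_scale_equivariance(self, random_slice_and_mask, cor_center):
        """Scaling every FI pixel by c scales every annulus mean by c."""
        fi, mask = random_slice_and_mask
        c = 0.37
        scaled = FatFractionSlice(fi.values * c)
        p = build_radial_profile(fi, mask, cor_center)
        ps = build_radial_profile(scaled, mask, cor_center)
        assert np.allclose(ps.mean_fi, c * p.mean_fi, equal_nan=True)


class TestOverallMean:
    def test_uniform_field(self, cor_center):
        fi = FatFractionSlice(np.full((4, 4), 20.0))
        mask = MuscleMask(np.ones((4, 4), bool), muscle="psoas")
        assert overall_mean_fi(fi, mask) == pytest.approx(20.0)

    def test_half_and_half(self):
        values = np.zeros((4, 4))
        values[:2] = 50.0
        mask = MuscleMask(np.ones((4, 4), bool), muscle="psoas")
        assert overall_mean_fi(FatFractionSlice(values), mask) == pytest.approx(25.0)

    def test_conservation_identity(self, random_slice_and_mask, cor_center):
        """Pixel-count-weighted mean of raw annulus means equals the overall mean."""
        fi, mask = random_slice_and_mask
        p = build_radial_profile(fi, mask, cor_center)
        weighted = np.nansum(p.mean_fi * p.pixel_count) / p.pixel_count.sum()
        assert weighted == pytest.approx(overall_mean_fi(fi, mask), abs=1e-9)


class TestSmoothProfile:
    def test_constant_curve_unchanged(self):
        p = smooth_profile(_profile([12.0] * 6))
        assert np.allclose(p.mean_fi, 12.0)
        assert p.smoothed

    def test_three_point_average_center(self):
        p = smooth_profile(_profile([0.0, 30.0, 0.0]))
        assert p.mean_fi[1] == pytest.approx(10.0)

    def test_one_sided_endpoints(self):
        p = smooth_profile(_profile([10.0, 20.0, 30.0, 40.0]))
        assert np.allclose(p.mean_fi, [15.0, 20.0, 30.0, 35.0])

    def test_interior_gap_interpolated_first(self):
        p = smooth_profile(_profile([10.0, np.nan, 30.0]))
        # gap filled to 20 before averaging
        assert p.mean_fi[1] == pytest.approx(20.0)
        assert p.mean_fi[0] == pytest.approx(15.0)

    def test_leading_missing_annuli_stay_missing(self):
        p = smooth_profile(_profile([np.nan, 10.0, 20.0, 30.0]))
        assert np.isnan(p.mean_fi[0])


class TestNormalizeProfile:
    def test_linear_ramp_preserved(self):
        ramp = np.linspace(0.0, 50.0, 11)
        out = normalize_profile(_profile(ramp), n_nodes=101)
        assert np.allclose(out.fi, 0.5 * out.nodes, atol=1e-12)

    def test_endpoints_preserved_exactly(self, rng):
        curve = rng.uniform(0, 100, 17)
        out = normalize_profile(_profile(curve), n_nodes=101)
        assert out.fi[0] == curve[0]
        assert out.fi[-1] == curve[-1]

    def test_matches_piecewise_linear_oracle(self, rng):
        """Node values equal an independent pointwise linear evaluation."""
        curve = rng.uniform(0, 100, 13)
        out = normalize_profile(_profile(curve), n_nodes=101)
        for j, x in enumerate(out.nodes):
            pos = x / 100.0 * 12.0  # annulus coordinate
            lo = int(np.floor(pos))
            hi = min(lo + 1, 12)
            frac = pos - lo
            expected = (1 - frac) * curve[lo] + frac * curve[hi]
            assert out.fi[j] == pytest.approx(expected, abs=1e-9)

    def test_requires_two_occupied_annuli(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalize_profile(_profile([np.nan, 5.0, np.nan]))

    def test_idempotent_on_node_aligned_curve(self, rng):
        curve = rng.uniform(0, 100, 101)
        out = normalize_profile(_profile(curve), n_nodes=101)
        assert np.allclose(out.fi, curve, atol=1e-9)

    def test_offset_span_maps_to_full_width(self):
        mean_fi = np.full(10, np.nan)
        mean_fi[4:8] = [1.0, 2.0, 3.0, 4.0]
        out = normalize_profile(_profile(mean_fi), n_nodes=4)
        assert np.allclose(out.fi, [1.0, 2.0, 3.0, 4.0])


class TestPeaks:
    def test_unique_maximum(self):
        fi = np.zeros(101)
        fi[16] = 49.3
        pk = detect_peak(_normalized(fi))
        assert pk.peak_fi == pytest.approx(49.3)
        assert pk.peak_depth == pytest.approx(16.0)
        assert pk.region == "deep"

    def test_constant_curve_ties_to_depth_zero(self):
        pk = detect_peak(_normalized(np.full(101, 5.0)))
        assert pk.peak_depth == 0.0
        assert pk.region == "deep"

    def test_tie_breaks_toward_smaller_depth(self):
        fi = np.zeros(101)
        fi[10] = fi[80] = 42.0
        pk = detect_peak(_normalized(fi))
        assert pk.peak_depth == pytest.approx(10.0)

    def test_region_boundaries(self):
        fi = np.zeros(101)
        fi[50] = 10.0
        assert detect_peak(_normalized(fi)).region == "intermediate"
        fi = np.zeros(101)
        fi[90] = 10.0
        assert detect_peak(_normalized(fi)).region == "superficial"

    def test_prevalence_all_deep(self):
        profiles = []
        for _ in range(5):
            fi = np.zeros(101)
            fi[5] = 30.0
            profiles.append(_normalized(fi))
        assert peak_prevalence(profiles, region="deep") == 1.0

    def test_prevalence_fraction(self):
        profiles = []
        for depth in (5, 50, 50, 90):
            fi = np.zeros(101)
            fi[depth] = 30.0
            profiles.append(_normalized(fi))
        assert peak_prevalence(profiles, region="deep") == 0.25

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            peak_prevalence([], region="deep")


class TestProfileCsvRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        profiles = [
            _normalized(rng.uniform(0, 100, 11), subject_id=f"s{i}", smoothed=True)
            for i in range(3)
        ]
        write_profiles_csv(profiles, tmp_path / "p.csv")
        back = read_profiles_csv(tmp_path / "p.csv")
        assert len(back) == 3
        by_id = {p.subject_id: p for p in back}
        for p in profiles:
            assert np.allclose(by_id[p.subject_id].fi, p.fi)
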