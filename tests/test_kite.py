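"""Kite geometry: construction, derived traits, and analytic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hempkite.kite import (
    ArchitectureMeasurements,
    KiteValidationError,
    build_kite,
    canopy_density,
    floral_biomass_per_area,
    internode_length,
    kite_branch_angle,
    kite_volume,
    max_circularity_search,
    shape_ratios,
    specific_kite_area,
    derive_kite_traits,
)


def valid_kites():
    """Strategy over measurement sets satisfying trkl < mcdh < ht."""
    return st.builds(
        lambda ht, mcd, u, t: ArchitectureMeasurements(
            ht=ht, mcd=mcd, mcdh=t + u * (ht - t), trkl=t),
        ht=st.floats(50, 400),
        mcd=st.floats(10, 300),
        u=st.floats(0.05, 0.95),
        t=st.floats(0, 40),
    ).filter(lambda m: m.trkl < m.mcdh < m.ht)


class TestBuildKite:
    def test_square_kite(self):
        k = build_kite(ArchitectureMeasurements(ht=100, mcd=100, mcdh=50, trkl=0))
        assert k.lower_leg == k.upper_leg == k.half_width == 50
        assert k.area == pytest.approx(0.5)
        assert k.hyp_ratio == pytest.approx(1.0)
        assert k.branch_angle == pytest.approx(45.0)
        assert k.circularity == pytest.approx(math.pi / 4, abs=1e-12)

    def test_population_mean_kite(self):
        # hand arithmetic at the trial's population-mean measurements
        k = build_kite(
            ArchitectureMeasurements(ht=157.7, mcd=125.9, mcdh=85.9, trkl=12.2))
        assert k.area == pytest.approx(0.916, abs=0.001)
        assert k.branch_angle == pytest.approx(40.5, abs=0.1)
        assert k.hyp_ratio == pytest.approx(0.985, abs=0.001)
        assert k.circularity == pytest.approx(0.777, abs=0.001)

    @pytest.mark.parametrize(
        "kw, field",
        [
            (dict(ht=100, mcd=100, mcdh=100, trkl=0), "mcdh"),   # upper leg zero
            (dict(ht=100, mcd=100, mcdh=5, trkl=10), "mcdh"),    # below trunk
            (dict(ht=-1, mcd=100, mcdh=50, trkl=0), "ht"),
            (dict(ht=100, mcd=0, mcdh=50, trkl=0), "mcd"),
        ],
    )
    def test_degenerate_rejected_naming_field(self, kw, field):
        with pytest.raises(KiteValidationError, match=field):
            build_kite(ArchitectureMeasurements(**kw))

    @given(valid_kites())
    def test_invariant_identities(self, m):
        k = build_kite(m)
        assert k.lower_hyp == pytest.approx(
            math.hypot(k.half_width, k.lower_leg))
        assert k.upper_hyp == pytest.approx(
            math.hypot(k.half_width, k.upper_leg))
        # area from the shoelace formula on the four vertices (cm² -> m²)
        w = k.half_width
        verts = [(0, m.trkl), (w, m.mcdh), (0, m.ht), (-w, m.mcdh)]
        shoe = 0.5 * abs(sum(
            x1 * y2 - x2 * y1
            for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1])))
        assert k.area == pytest.approx(shoe / 1e4, rel=1e-9)
        assert 0 < k.circularity <= math.pi / 4 + 1e-12
        assert 0 < k.branch_angle < 90

    @given(valid_kites(), st.floats(0.5, 3.0))
    def test_scale_invariance(self, m, s):
        k1 = build_kite(m)
        k2 = build_kite(ArchitectureMeasurements(
            ht=s * m.ht, mcd=s * m.mcd, mcdh=s * m.mcdh, trkl=s * m.trkl))
        assert k2.circularity == pytest.approx(k1.circularity, rel=1e-9)
        assert k2.hyp_ratio == pytest.approx(k1.hyp_ratio, rel=1e-9)
        assert k2.branch_angle == pytest.approx(k1.branch_angle, rel=1e-9)
        assert k2.area == pytest.approx(s**2 * k1.area, rel=1e-9)
        assert k2.volume == pytest.approx(s**3 * k1.volume, rel=1e-9)


class TestCircularityMaximum:
    def test_grid_argmax_is_45_degrees(self):
        angle, circ = max_circularity_search()
        assert angle == pytest.approx(45.0, abs=0.1)
        assert circ == pytest.approx(math.pi / 4, abs=1e-4)
        assert round(circ, 2) == 0.79

    @given(valid_kites())
    def test_pi_over_4_bound_with_square_equality(self, m):
        k = build_kite(m)
        assert k.circularity <= math.pi / 4 + 1e-12
        if k.circularity > math.pi / 4 - 1e-9:
            assert k.lower_leg == pytest.approx(k.half_width, rel=1e-3)
            assert k.upper_leg == pytest.approx(k.half_width, rel=1e-3)


class TestBranchAngle:
    def test_isoceles_45(self):
        k = build_kite(ArchitectureMeasurements(ht=200, mcd=100, mcdh=50, trkl=0))
        assert kite_branch_angle(k) == pytest.approx(45.0)

    def test_table_mean_value(self):
        k = build_kite(
            ArchitectureMeasurements(ht=157.7, mcd=125.9, mcdh=85.9, trkl=12.2))
        assert kite_branch_angle(k) == pytest.approx(40.5, abs=0.1)

    def test_columnar_limit(self):
        angles = [
            build_kite(ArchitectureMeasurements(
                ht=100, mcd=w, mcdh=50, trkl=0)).branch_angle
            for w in (10, 1, 0.1, 0.01)
        ]
        assert all(a2 < a1 for a1, a2 in zip(angles, angles[1:]))
        assert angles[-1] < 0.01


class TestVolumeAndDensity:
    def test_bicone_volume(self):
        k = build_kite(ArchitectureMeasurements(ht=100, mcd=100, mcdh=50, trkl=0))
        assert kite_volume(k) == pytest.approx((math.pi / 3) * 0.25 * 1.0, rel=1e-9)

    def test_width_scaling_quadratic(self):
        k1 = build_kite(ArchitectureMeasurements(ht=100, mcd=50, mcdh=50, trkl=0))
        k2 = build_kite(ArchitectureMeasurements(ht=100, mcd=100, mcdh=50, trkl=0))
        assert k2.volume == pytest.approx(4 * k1.volume, rel=1e-9)

    def test_density(self):
        k = build_kite(ArchitectureMeasurements(ht=100, mcd=100, mcdh=50, trkl=0))
        assert canopy_density(0.0, k) == 0.0
        assert canopy_density(1.0, k) == pytest.approx(3.82, abs=0.01)

    def test_density_zero_mass_and_errors(self):
        k = build_kite(ArchitectureMeasurements(ht=100, mcd=100, mcdh=50, trkl=0))
        with pytest.raises(ValueError):
            canopy_density(-1.0, k)


class TestScalarTraits:
    def test_specific_kite_area(self):
        k = build_kite(
            ArchitectureMeasurements(ht=157.7, mcd=125.9, mcdh=85.9, trkl=12.2))
        ska = specific_kite_area(k, 1.84)
        assert ska == pytest.approx(0.498, abs=0.002)
        assert k.area / (1.84 * ska) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(ValueError):
            specific_kite_area(k, 0.0)

    def test_floral_biomass_per_area(self):
        assert floral_biomass_per_area(1.11, 125.9) == pytest.approx(0.700, abs=0.001)
        assert floral_biomass_per_area(0.0, 50.0) == 0.0
        assert floral_biomass_per_area(0.9, 100.0) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            floral_biomass_per_area(1.0, 0.0)

    @pytest.mark.parametrize("bpair, inl", [(10, 5.0), (7.45, 6.711), (4, 12.5)])
    def test_internode_length(self, bpair, inl):
        assert internode_length(bpair) == pytest.approx(inl, abs=0.001)

    def test_internode_rejects_below_one(self):
        with pytest.raises(ValueError):
            internode_length(0.5)

    def test_shape_ratios(self):
        m = ArchitectureMeasurements(ht=100, mcd=100, mcdh=50)
        assert shape_ratios(m) == pytest.approx((1.0, 0.5))
        m = ArchitectureMeasurements(ht=157.7, mcd=125.9, mcdh=85.9)
        r1, r2 = shape_ratios(m)
        assert r1 == pytest.approx(0.798, abs=0.001)
        assert r2 == pytest.approx(0.545, abs=0.001)


def test_derive_kite_traits_table(trial_df):
    out = derive_kite_traits(trial_df)
    for col in ("KITE", "KHR", "KBA", "KC", "VOL_KITE", "INL"):
        assert col in out.columns
    ok = out[["KITE", "KC"]].dropna()
    assert len(ok) == len(out)            # generator only makes valid kites
    assert (out["KC"] <= math.pi / 4 + 1e-9).all()
    assert np.allclose(out["INL"], 50.0 / trial_df["BPAIR"])
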