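import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_hyp

from conftest import make_biopsy, make_glomerulus
from podometry import stereology as st
from podometry.errors import ValidationError
from podometry.measurements import BiopsyMeasurement, OpticalConfig


def closed_form_thickness(lam, n, na):
    # independent direct evaluation of the axial-resolution formula, in um
    return 0.88 * lam / (n - math.sqrt(n**2 - na**2)) / 1000.0


class TestOpticalSectionThickness:
    def test_reference_value(self):
        t = st.optical_section_thickness(OpticalConfig(405.0, 1.515, 1.25))
        assert round(t, 3) == 0.541

    def test_488nm(self):
        t = st.optical_section_thickness(OpticalConfig(488.0, 1.515, 1.25))
        assert t == pytest.approx(closed_form_thickness(488.0, 1.515, 1.25))
        assert round(t, 4) == 0.6516

    def test_strictly_decreasing_in_na(self):
        nas = np.linspace(0.2, 1.4, 20)
        values = [st.optical_section_thickness(OpticalConfig(405, 1.515, na)) for na in nas]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_strictly_increasing_in_wavelength(self):
        lams = np.linspace(350, 650, 15)
        values = [st.optical_section_thickness(OpticalConfig(lam, 1.515, 1.25)) for lam in lams]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestMeanGlomerularArea:
    def test_mean(self):
        b = BiopsyMeasurement(
            "p",
            (
                make_glomerulus("g1", area=10000.0, snp=0.0),
                make_glomerulus("g2", area=20000.0, snp=0.0),
            ),
        )
        assert st.mean_glomerular_area(b) == 15000.0

    def test_single(self):
        b = BiopsyMeasurement("p", (make_glomerulus(area=12345.0, snp=0.0),))
        assert st.mean_glomerular_area(b) == 12345.0

    def test_brute_force_sum_oracle(self, rng):
        areas = rng.uniform(4000, 30000, size=14)
        gloms = tuple(
            make_glomerulus(f"g{i}", area=float(a), snp=0.0) for i, a in enumerate(areas)
        )
        b = BiopsyMeasurement("p", gloms)
        total = 0.0
        for a in areas:
            total += a
        assert st.mean_glomerular_area(b) == pytest.approx(total / 14, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            st.mean_glomerular_area(BiopsyMeasurement("p", ()))


class TestGlomerularVolume:
    def test_reference(self):
        # (1.382 / 1.01) * 10000 ** 1.5
        assert st.glomerular_volume(10000.0) == pytest.approx(1.3683168e6, rel=1e-6)

    def test_zero(self):
        assert st.glomerular_volume(0.0) == 0.0

    def test_negative_errors(self):
        with pytest.raises(ValidationError):
            st.glomerular_volume(-1.0)

    @given(
        st_hyp.floats(min_value=100.0, max_value=1e6),
        st_hyp.floats(min_value=0.1, max_value=10.0),
    )
    def test_homogeneous_degree_three_halves(self, area, k):
        scaled = st.glomerular_volume(k * area)
        assert scaled == pytest.approx(k**1.5 * st.glomerular_volume(area), rel=1e-9)

    def test_sphere_mean_area_recovery(self, rng):
        # sectioning a sphere of radius R uniformly gives mean area 2/3 pi R^2;
        # the shape-coefficient estimator on that mean recovers the volume
        radius = 90.0
        offsets = rng.uniform(-radius, radius, size=20000)
        mean_area = float(np.mean(math.pi * (radius**2 - offsets**2)))
        vol = st.glomerular_volume(mean_area)
        truth = 4.0 / 3.0 * math.pi * radius**3
        assert vol == pytest.approx(truth, rel=0.05)


class TestDiameterCorrection:
    def test_custom_factor_reference(self):
        cfg = st.StereologyConfig(
            diameter_correction_mode="custom", custom_correction_factor=1.3612
        )
        assert st.true_nuclear_diameter(7.31, cfg) == pytest.approx(9.95, abs=0.005)

    def test_four_over_pi(self):
        assert st.true_nuclear_diameter(7.31) == pytest.approx(4 / math.pi * 7.31)

    def test_identity(self):
        cfg = st.StereologyConfig(diameter_correction_mode="identity")
        assert st.true_nuclear_diameter(3.3, cfg) == 3.3

    def test_nonpositive_errors(self):
        with pytest.raises(ValidationError):
            st.true_nuclear_diameter(0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            st.StereologyConfig(diameter_correction_mode="nope")


def _density_biopsy():
    # 100 nuclei of apparent diameter 7.31 over a total area of 1e5 um^2
    gloms = tuple(
        make_glomerulus(f"g{i}", area=10000.0, diameters=(7.31,) * 10, snp=0.0)
        for i in range(10)
    )
    return BiopsyMeasurement("p", gloms)


class TestPodocyteDensity:
    def test_reference(self):
        cfg = st.StereologyConfig(density_uses_corrected_diameter=False)
        density = st.podocyte_density(_density_biopsy(), cfg)
        thickness = st.optical_section_thickness(OpticalConfig())
        expected = 100 / (1e5 * (7.31 + thickness))
        assert density == pytest.approx(expected, rel=1e-12)
        assert density == pytest.approx(1.2737e-4, rel=1e-3)

    def test_linearity_in_count(self):
        cfg = st.StereologyConfig(density_uses_corrected_diameter=False)
        base = st.podocyte_density(_density_biopsy(), cfg)
        doubled_gloms = tuple(
            make_glomerulus(f"g{i}", area=10000.0, diameters=(7.31,) * 20, snp=0.0)
            for i in range(10)
        )
        doubled = st.podocyte_density(BiopsyMeasurement("p", doubled_gloms), cfg)
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_no_nuclei_errors(self):
        b = BiopsyMeasurement("p", (make_glomerulus(diameters=(), snp=0.0),))
        with pytest.raises(ValidationError):
            st.podocyte_density(b)


class TestVolumes:
    def test_podocytes_per_tuft(self):
        assert st.podocytes_per_tuft(76e-6, 3.67e6) == pytest.approx(278.92, abs=0.01)
        assert st.podocytes_per_tuft(0.0, 5.0) == 0.0

    def test_snp_fraction(self):
        b = BiopsyMeasurement(
            "p",
            (
                make_glomerulus("g1", area=10000.0, snp=1300.0),
                make_glomerulus("g2", area=10000.0, snp=0.0),
            ),
        )
        assert st.snp_fraction(b) == pytest.approx(0.065)

    def test_snp_fraction_saturation(self):
        b = BiopsyMeasurement("p", (make_glomerulus(area=5000.0, snp=5000.0),))
        assert st.snp_fraction(b) == 1.0

    def test_nuclear_volume_reference(self):
        v = st.podocyte_nuclear_volume(7.31)
        assert v == pytest.approx(4 * math.pi / 3 * (2 / math.pi * 7.31) ** 3, rel=1e-12)
        assert v == pytest.approx(422.1, abs=0.2)

    def test_nuclear_volume_unit_radius(self):
        assert st.podocyte_nuclear_volume(math.pi / 2) == pytest.approx(4 * math.pi / 3)

    @given(st_hyp.floats(min_value=0.5, max_value=20.0), st_hyp.floats(min_value=0.1, max_value=5.0))
    def test_nuclear_volume_cubic_homogeneity(self, d, k):
        assert st.podocyte_nuclear_volume(k * d) == pytest.approx(
            k**3 * st.podocyte_nuclear_volume(d), rel=1e-9
        )

    def test_cytoplasmic_volume(self):
        v = st.podocyte_cytoplasmic_volume(3.67e6, 0.13, 279.0)
        assert v == pytest.approx(1710.0, abs=1.0)
        assert st.podocyte_cytoplasmic_volume(3.67e6, 0.0, 279.0) == 0.0
        halved = st.podocyte_cytoplasmic_volume(3.67e6, 0.13, 558.0)
        assert halved == pytest.approx(v / 2)

    def test_cytoplasmic_requires_positive_n(self):
        with pytest.raises(ValidationError):
            st.podocyte_cytoplasmic_volume(1.0, 0.1, 0.0)

    def test_total_and_nc_ratio(self):
        assert st.total_podocyte_volume(399.0, 1425.0) == 1824.0
        assert st.total_podocyte_volume(0.0, 0.0) == 0.0
        assert 399.0 / 1425.0 == pytest.approx(0.28, abs=0.0004)

    def test_vv_pod_glom(self):
        assert st.vv_pod_glom(1834.0, 279.0, 3.0e6) == pytest.approx(0.17056, abs=1e-4)
        assert st.vv_pod_glom(1834.0, 0.0, 3.0e6) == 0.0
        with pytest.raises(ValidationError):
            st.vv_pod_glom(1.0, 1.0, 0.0)

    def test_vv_above_one_warns(self):
        with pytest.warns(UserWarning):
            assert st.vv_pod_glom(1e6, 100.0, 1e6) > 1


class TestComputePodometrics:
    def test_deterministic_and_identities(self, rng):
        areas = rng.uniform(8000, 20000, size=9)
        gloms = tuple(
            make_glomerulus(
                f"g{i}",
                area=float(a),
                diameters=tuple(float(d) for d in rng.uniform(6, 9, size=8)),
                snp=float(0.13 * a),
            )
            for i, a in enumerate(areas)
        )
        b = BiopsyMeasurement("p", gloms)
        res1 = st.compute_podometrics(b)
        res2 = st.compute_podometrics(b)
        assert res1 == res2
        # closure identities
        assert res1.total_podocyte_volume == pytest.approx(
            res1.nuclear_volume + res1.cytoplasmic_volume, rel=1e-9
        )
        assert res1.vv_pod_glom == pytest.approx(
            res1.total_podocyte_volume * res1.podocytes_per_tuft / res1.glomerular_volume,
            rel=1e-9,
        )
        # when the cytoplasm comes from the stain fraction, the volume fraction
        # decomposes exactly into stain fraction + nuclear contribution
        nuclear_part = (
            res1.nuclear_volume * res1.podocytes_per_tuft / res1.glomerular_volume
        )
        assert res1.vv_pod_glom == pytest.approx(res1.snp_fraction + nuclear_part, rel=1e-9)

    def test_zero_nuclei_biopsy_errors(self):
        gloms = tuple(
            make_glomerulus(f"g{i}", score=4, diameters=(), snp=0.0) for i in range(8)
        )
        with pytest.raises(ValidationError):
            st.compute_podometrics(BiopsyMeasurement("p", gloms))

    def test_results_frame_echoes_config(self):
        b = make_biopsy()
        cfg = st.StereologyConfig(diameter_correction_mode="identity")
        frame = st.results_to_frame([st.compute_podometrics(b, cfg)], cfg)
        assert frame.loc[0, "cfg_correction_mode"] == "identity"
        assert frame.loc[0, "cfg_beta"] == 1.382
        assert frame.loc[0, "cfg_d"] == 1.01
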