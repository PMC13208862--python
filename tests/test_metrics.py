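"""Printability metrics: SR, UF, Pr, collapse, yield stress, fusion."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from printbench.imageops import BinaryMask, label_particles
from printbench.metrics import (MaterialParams, NozzleSpec,
                                apparent_yield_stress, collapse_angle,
                                collapse_rate, deflection_angle_for_stress,
                                fusion_analysis, measure_line_width,
                                printability_index, spreading_ratio,
                                strand_width_from_ink_area, uniformity_ratio)
from printbench.patterns import ChirpParams, Toolpath, line_toolpath, \
    serpentine_toolpath
from printbench.presets import pneumatic_deposition, screw_deposition
from printbench.render import DepositionModel, SagModel, render_sideview, \
    render_topview

NOZZLE = NozzleSpec(inner_diameter=0.41)
MATERIAL = MaterialParams()


class TestLineWidth:
    def test_nine_pixel_bar_run_length(self):
        m = np.zeros((40, 100), dtype=bool)
        m[10:19, :] = True  # 9 px tall bar
        r = measure_line_width(BinaryMask(m, scale=20))
        assert r.mean_mm == pytest.approx(0.45, abs=1e-9)
        assert r.sd_mm == pytest.approx(0.0, abs=1e-9)

    def test_rendered_width_recovered_subpixel(self):
        t = line_toolpath(30, 0.41)
        img = render_topview(t, DepositionModel(spread_ratio=0.447 / 0.41), scale=40)
        r = measure_line_width(img)
        assert r.mean_mm == pytest.approx(0.447, abs=1 / 40)

    def test_rotated_bar_same_width(self):
        t45 = Toolpath(vertices=[[0.0, 0.0], [20.0, 20.0]], extrude=[True],
                       widths=[0.6], layers=[0], metadata={"pattern": "line"})
        t0 = line_toolpath(20, 0.6)
        w45 = measure_line_width(render_topview(t45, DepositionModel(), scale=40))
        w0 = measure_line_width(render_topview(t0, DepositionModel(), scale=40))
        assert w45.mean_mm == pytest.approx(w0.mean_mm, rel=0.03)

    def test_broken_sections_excluded_and_counted(self):
        t = line_toolpath(30, 0.6)
        img = render_topview(t, DepositionModel(), scale=20)
        img.pixels[:, 300:320] = 230  # erase a 1 mm stretch mid-filament
        r = measure_line_width(img)
        assert r.n_broken > 0
        assert r.mean_mm == pytest.approx(0.6, abs=0.05)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            measure_line_width(BinaryMask(np.zeros((10, 10), bool), scale=20))


class TestSpreadingRatio:
    @pytest.mark.parametrize("w,expected", [(0.41, 1.0), (0.747, 1.82), (0.447, 1.09)])
    def test_study_values(self, w, expected):
        assert spreading_ratio(w, NOZZLE) == pytest.approx(expected, abs=0.005)

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            spreading_ratio(0.0, NOZZLE)


class TestUniformityRatio:
    def test_perfect_rectangle_is_unity(self):
        t = line_toolpath(30, 0.6)
        lm = uniformity_ratio(render_topview(t, DepositionModel(), scale=40))
        assert lm.uniformity == pytest.approx(1.0, abs=0.01)

    def test_ratio_identity(self):
        t = line_toolpath(30, 0.6)
        lm = uniformity_ratio(render_topview(t, DepositionModel(), scale=40))
        assert lm.uniformity == lm.measured_perimeter / lm.theoretical_perimeter

    def test_sinusoidal_boundary_matches_quadrature_oracle(self):
        # both edges displaced by a*sin(2*pi*x/lam): arc length of each edge
        # is integral sqrt(1 + (a k cos(kx))^2) dx
        a, lam, w, L, scale = 0.05, 2.0, 0.6, 30.0, 40
        k = 2 * math.pi / lam
        cols = np.arange(int(L * scale))
        x = (cols + 0.5) / scale
        rows = np.arange(int((w + 4 * a + 2) * scale))
        y = (rows + 0.5) / scale - (w / 2 + 2 * a + 1)
        disp = a * np.sin(k * x)
        mask = (y[:, None] <= w / 2 + disp[None, :]) & \
               (y[:, None] >= -w / 2 - disp[None, :])
        lm = uniformity_ratio(BinaryMask(mask, scale=scale))
        arc = quad(lambda t: math.sqrt(1 + (a * k * math.cos(k * t)) ** 2), 0, L,
                   limit=200)[0]
        expected = (2 * arc + 2 * lm.mean_width) / (2 * L + 2 * lm.mean_width)
        # the measurement window trims the ends, but the boundary is periodic
        assert lm.uniformity > 1.0
        assert lm.uniformity == pytest.approx(expected, rel=0.02)

    def test_pneumatic_preset_reaches_study_uniformity(self):
        ufs = []
        for seed in range(3):
            t = line_toolpath(30, 0.41)
            img = render_topview(t, pneumatic_deposition(seed=seed), scale=40)
            ufs.append(uniformity_ratio(img).uniformity)
        assert np.mean(ufs) == pytest.approx(1.04, abs=0.02)

    def test_split_filament_rejected(self):
        m = np.zeros((60, 200), dtype=bool)
        m[10:20, :] = True
        m[40:50, :] = True
        with pytest.raises(ValueError, match="multiple"):
            uniformity_ratio(BinaryMask(m, scale=20))


class TestPrintabilityIndex:
    def test_square_is_unity_exactly(self):
        assert printability_index((4.0, 1.0)) == 1.0

    def test_disk_closed_form(self):
        r = 2.0
        assert printability_index((2 * math.pi * r, math.pi * r**2)) == \
            pytest.approx(math.pi / 4)

    def test_two_to_one_rectangle_closed_form(self):
        s = 3.0
        assert printability_index((6 * s, 2 * s**2)) == pytest.approx(1.125)

    @pytest.mark.parametrize("shape,expected", [("square", 1.0),
                                                ("disk", math.pi / 4),
                                                ("rect", 1.125)])
    def test_rasterized_closed_forms(self, shape, expected):
        scale = 20
        n = 200
        yy, xx = np.mgrid[0:n, 0:n]
        if shape == "square":
            m = (xx >= 40) & (xx < 140) & (yy >= 40) & (yy < 140)
        elif shape == "disk":
            m = (xx - 100) ** 2 + (yy - 100) ** 2 <= 50**2
        else:  # 6 x 3 mm
            m = (xx >= 40) & (xx < 160) & (yy >= 70) & (yy < 130)
        rec = label_particles(BinaryMask(m, scale=scale))[0]
        assert printability_index(rec) == pytest.approx(expected, abs=0.03)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            printability_index((0.0, 1.0))


class TestCollapse:
    def test_horizontal_band_zero_angle(self):
        img = render_sideview(SagModel(span=32, max_sag=0.0), scale=20)
        assert collapse_angle(img).theta_deg == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("sag,angle", [(1.273, 9.04), (2.025, 14.2),
                                           (3.151, 21.5)])
    def test_parabolic_sag_angle_matches_support_tangent(self, sag, angle):
        img = render_sideview(SagModel(span=32, max_sag=sag), scale=20)
        assert collapse_angle(img).theta_deg == pytest.approx(angle, abs=0.3)

    def test_rupture_flagged(self):
        img = render_sideview(SagModel(span=32, max_sag=1.0), scale=20)
        cols = img.pixels.shape[1] // 2
        img.pixels[:, cols - 10 : cols + 10] = 230  # erase midspan
        assert collapse_angle(img).ruptured

    def test_collapse_rate_parabola_closed_form(self):
        # enclosed parabola segment area (2/3) s L over span x floor H
        img = render_sideview(SagModel(span=32, max_sag=3.151), scale=20)
        cm = collapse_rate(img, reference_depth=10.0)
        assert cm.collapse_rate == pytest.approx(100 * 2 * 3.151 / (3 * 10), rel=0.02)

    def test_collapse_rate_identity_and_monotonicity(self):
        rates = []
        for sag in (0.5, 1.5, 3.0):
            img = render_sideview(SagModel(span=32, max_sag=sag), scale=20)
            cm = collapse_rate(img, reference_depth=10.0)
            assert cm.collapse_rate == pytest.approx(
                100 * (cm.theoretical_area - cm.actual_area) / cm.theoretical_area)
            rates.append(cm.collapse_rate)
        assert rates == sorted(rates)

    def test_sag_below_floor_rejected(self):
        img = render_sideview(SagModel(span=32, max_sag=3.0), scale=20)
        with pytest.raises(ValueError, match="floor"):
            collapse_rate(img, reference_depth=2.0)


class TestApparentYieldStress:
    @pytest.mark.parametrize("theta,sigma", [(21.5, 428), (14.2, 640), (9.04, 998)])
    def test_study_flow_rate_series(self, theta, sigma):
        assert apparent_yield_stress(theta, MATERIAL, 16.0) == \
            pytest.approx(sigma, rel=0.01)

    def test_ninety_degrees_gives_rho_g_l(self):
        assert apparent_yield_stress(90.0, MATERIAL, 16.0) == \
            pytest.approx(1000 * 9.81 * 0.016)

    def test_inversion_roundtrips_exactly(self):
        for sigma in (400.0, 650.0, 1000.0):
            theta = deflection_angle_for_stress(sigma, MATERIAL, 16.0)
            assert apparent_yield_stress(theta, MATERIAL, 16.0) == \
                pytest.approx(sigma, rel=1e-9)

    def test_vanishing_deflection_rejected_as_above_measurable(self):
        with pytest.raises(ValueError, match="above the measurable"):
            apparent_yield_stress(0.0, MATERIAL, 16.0)

    def test_stress_below_load_has_no_angle(self):
        with pytest.raises(ValueError):
            deflection_angle_for_stress(50.0, MATERIAL, 16.0)


class TestFusion:
    def test_geometric_open_closed_rule(self):
        t = serpentine_toolpath(ChirpParams(x_range=(0, 50)), commanded_width=0.41)
        img = render_topview(t, DepositionModel(spread_ratio=0.95 / 0.41), scale=20)
        fr = fusion_analysis(img, t.metadata)
        for gap in fr.gaps:
            if gap.spacing > 0.95 + 0.1:
                assert gap.open
            elif gap.spacing < 0.95 - 0.1:
                assert not gap.open
        assert fr.line_thickness == pytest.approx(0.95, abs=0.03)
        assert fr.lmin == pytest.approx(
            min(g.spacing for g in fr.gaps if g.spacing > 0.95), abs=0.05)

    def test_all_gaps_open_when_spacing_generous(self):
        # unmodulated wave: constant spacing pi/F far above the strand width
        p = ChirpParams(base_freq=1.2, chirp_rate=1.0, x_range=(0, 20))
        t = serpentine_toolpath(p, commanded_width=0.41)
        img = render_topview(t, DepositionModel(), scale=20)
        fr = fusion_analysis(img, t.metadata)
        assert all(g.open for g in fr.gaps)
        assert fr.lmin == pytest.approx(math.pi / 1.2, abs=0.01)

    def test_system_presets_reproduce_lmin_ordering(self):
        t = serpentine_toolpath(ChirpParams(x_range=(0, 50)), commanded_width=0.41)
        results = {}
        for name, model in (("screw", screw_deposition(100.0, seed=1)),
                            ("pneumatic", pneumatic_deposition(seed=1))):
            img = render_topview(t, model, scale=20)
            results[name] = fusion_analysis(img, t.metadata).lmin
        assert results["screw"] < results["pneumatic"]

    def test_missing_leg_flagged(self):
        t = serpentine_toolpath(ChirpParams(x_range=(0, 50)), commanded_width=0.41)
        img = render_topview(t, DepositionModel(), scale=20)
        legs = t.metadata["leg_positions"]
        ox, oy = img.metadata["origin_mm"]
        c = int((legs[2] - ox) * 20)
        r0, r1 = int((-8 - oy) * 20), int((8 - oy) * 20)
        img.pixels[r0:r1, c - 8 : c + 8] = 230  # erase most of leg 2
        fr = fusion_analysis(img, t.metadata)
        assert 2 in fr.missing_legs


class TestParameterRecovery:
    @pytest.mark.parametrize("spread", [1.2, 1.85])
    @pytest.mark.parametrize("rough", [0.0, 0.05])
    def test_sr_and_uf_recovered_from_render(self, spread, rough):
        t = line_toolpath(30, 0.41)
        m = DepositionModel(spread_ratio=spread, roughness_amplitude=rough,
                            roughness_wavelength=0.4, seed=5)
        img = render_topview(t, m, scale=40)
        lm = uniformity_ratio(img, nozzle=NOZZLE)
        truth = img.metadata["strand_truth"][0]
        assert lm.spreading_ratio == pytest.approx(spread, abs=0.03)
        assert lm.uniformity == pytest.approx(truth["uf"], abs=0.02)


class TestStrandWidthInversion:
    @pytest.mark.parametrize("w", [0.41, 0.6, 0.8])
    def test_roundtrips_strip_union_area(self, w):
        area = 2 * 6 * 30 * w - 36 * w**2
        assert strand_width_from_ink_area(area, 30.0, 6) == pytest.approx(w, rel=1e-9)
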