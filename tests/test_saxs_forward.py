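"""Debye forward model against analytic oracles, plus profile transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from micelle_ensemble import (SaxsConfig, ScatteringProfile, analytic_shape,
                              build_hydration_shell, debye_intensity,
                              guinier_rg, kratky_transform, pair_distribution,
                              porod_transform, rg_from_coords)
from micelle_ensemble.saxs_forward import contrast_weights, scatterer_amplitude


def gaussian_profile(rg, q=None, i0=1.0):
    q = np.linspace(0.001, 1.3 / rg, 64) if q is None else q
    return ScatteringProfile(q, i0 * np.exp(-(q * rg) ** 2 / 3.0))


class TestDebye:
    def test_single_bead_is_amplitude_squared(self, vacuum_cfg):
        m = analytic_shape("two_points", d=5.0).subset(np.array([True, False]))
        p = debye_intensity(m, vacuum_cfg)
        assert np.allclose(p.intensity, 1.0)  # f=1 bead

    def test_two_bead_closed_form(self, vacuum_cfg):
        d = 10.0
        m = analytic_shape("two_points", d=d)
        q = np.linspace(0.01, 0.6, 121)
        p = debye_intensity(m, vacuum_cfg, q=q)
        expected = 2.0 * (1.0 + np.sinc(q * d / np.pi))
        assert np.allclose(p.intensity, expected, rtol=1e-12)
        # at q = pi/d the sinc term vanishes: I/I(0) = 1/2
        p0 = debye_intensity(m, vacuum_cfg, q=np.array([1e-9, np.pi / d]))
        assert np.isclose(p0.intensity[1] / p0.intensity[0], 0.5, atol=1e-6)

    def test_i0_equals_total_amplitude_squared(self, ideal_micelle):
        cfg = SaxsConfig(n_q=8)
        g0 = contrast_weights(ideal_micelle, cfg).sum()
        p = debye_intensity(ideal_micelle, cfg, q=np.array([0.0, 0.01]))
        assert np.isclose(p.intensity[0], g0 ** 2, rtol=1e-10)

    def test_sphere_form_factor_oracle(self, sphere_r12, sphere_r12_profile):
        R = 12.0
        x = sphere_r12_profile.q * R
        f2 = (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        norm = sphere_r12_profile.intensity / sphere_r12_profile.intensity[0]
        m = x <= 5.0
        assert np.abs(norm[m] - f2[m]).max() < 0.02
        keep = m & (f2 >= 0.05)
        assert (np.abs(norm[keep] - f2[keep]) / f2[keep]).max() < 0.02

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rotation_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = analytic_shape("solid_sphere", radius=6.0, spacing=2.5,
                           rng_seed=seed)
        cfg = SaxsConfig(n_q=16, solvent_density=0.0, shell_contrast=0.0)
        base = debye_intensity(m, cfg).intensity
        rot = Rotation.random(random_state=rng)
        moved = m.transformed(rotation=rot, translation=rng.normal(0, 50, 3))
        after = debye_intensity(moved, cfg).intensity
        assert np.max(np.abs(after - base) / base) < 1e-10

    def test_empty_and_unknown_scatterer(self, vacuum_cfg):
        m = analytic_shape("two_points", d=3.0)
        m.scatterer[0] = "XX"
        with pytest.raises(KeyError):
            debye_intensity(m, vacuum_cfg)

    def test_excluded_volume_reduces_contrast(self):
        cfg = SaxsConfig()
        q = np.array([0.0, 0.1])
        g_vac = scatterer_amplitude("C", q, SaxsConfig(solvent_density=0.0))
        g_sol = scatterer_amplitude("C", q, cfg)
        assert np.all(g_sol < g_vac)


class TestHydrationShell:
    def test_zero_contrast_is_identity(self, ideal_micelle):
        cfg = SaxsConfig(shell_contrast=0.0)
        assert build_hydration_shell(ideal_micelle, cfg) is ideal_micelle

    def test_shell_bead_radii_bounds(self, sphere_r12):
        cfg = SaxsConfig(shell_contrast=0.06, shell_thickness=3.0,
                         shell_bead_spacing=2.0, shell_contact=1.6)
        out = build_hydration_shell(sphere_r12, cfg)
        shell = out.coords[out.group_tag == "SOLVENT"]
        assert len(shell) > 0
        r = np.linalg.norm(shell, axis=1)
        # beads sit beyond the solute surface but within contact+thickness of it
        assert r.min() > 12.0 - 1.0  # jittered surface beads may sit slightly in
        assert r.max() <= 12.0 + cfg.shell_contact + cfg.shell_thickness + 1e-9

    def test_rg_nondecreasing_with_shell_contrast(self, sphere_r12):
        rgs = []
        for contrast in (0.0, 0.03, 0.06):
            cfg = SaxsConfig(n_q=48, q_max=0.25, shell_contrast=contrast,
                             solvent_density=0.0)
            model = build_hydration_shell(sphere_r12, cfg)
            rg, _ = guinier_rg(debye_intensity(model, cfg))
            rgs.append(rg)
        assert rgs[0] <= rgs[1] <= rgs[2]
        assert rgs[2] > rgs[0]

    def test_guinier_agrees_with_coordinate_rg(self, sphere_r12):
        cfg = SaxsConfig(n_q=48, q_max=0.2)
        model = build_hydration_shell(sphere_r12, cfg)
        rg_q, _ = guinier_rg(debye_intensity(model, cfg))
        rg_x = rg_from_coords(model, weights=contrast_weights(model, cfg))
        assert abs(rg_q - rg_x) / rg_x < 0.03


class TestGuinier:
    def test_flat_profile_gives_zero(self):
        p = ScatteringProfile(np.linspace(0.01, 0.1, 20), np.ones(20))
        rg, i0 = guinier_rg(p)
        assert rg == 0.0 and np.isclose(i0, 1.0)

    def test_gaussian_roundtrip_rg_16p7(self):
        rg, i0 = guinier_rg(gaussian_profile(16.7, i0=2.5))
        assert abs(rg - 16.7) < 1e-6
        assert abs(i0 - 2.5) < 1e-6

    def test_window_iterated_to_qrg_limit(self):
        # profile that is Gaussian at low q but flattens at high q
        q = np.linspace(0.005, 0.6, 300)
        i = np.exp(-(q * 16.7) ** 2 / 3.0) + 1e-4
        rg, _ = guinier_rg(ScatteringProfile(q, i))
        assert abs(rg - 16.7) / 16.7 < 0.02

    def test_rising_profile_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError, match="slope"):
            guinier_rg(ScatteringProfile(q, np.exp(+q ** 2 * 50)))


class TestPairDistribution:
    def test_two_points_single_bin(self):
        m = analytic_shape("two_points", d=10.0)
        pr = pair_distribution(m, bin_width=1.0)
        assert pr.p.sum() == 1
        assert 10.0 <= pr.dmax <= 11.0

    def test_sphere_dmax_within_bin(self, sphere_r12):
        pr = pair_distribution(sphere_r12, bin_width=0.5)
        true = pdist(sphere_r12.coords).max()
        assert pr.dmax <= true + 0.5 + 1e-12
        assert pr.dmax >= true

    def test_hexamer_oxygen_distances_bracketed(self, ideal_micelle):
        pr = pair_distribution(ideal_micelle, selection="CALIX_O", bin_width=0.5)
        d = pdist(ideal_micelle.coords[ideal_micelle.group_tag == "CALIX_O"])
        assert pr.p.sum() == len(d)
        occupied = pr.r[pr.p > 0]
        assert occupied.min() >= d.min() - 0.5
        assert occupied.max() <= d.max() + 0.5

    def test_zero_beyond_dmax(self, ideal_micelle):
        pr = pair_distribution(ideal_micelle, bin_width=1.0)
        assert np.all(pr.p[pr.r > pr.dmax] == 0)

    def test_empty_selection_errors(self, sphere_r12):
        with pytest.raises(ValueError):
            pair_distribution(sphere_r12, selection="SOLVENT")

    def test_pr_fourier_consistency_with_debye(self, sphere_r12,
                                               sphere_r12_profile, vacuum_cfg):
        # I(q) = N*f^2 + 2 * sum_bins P(r) sinc(q r) for unit beads
        pr = pair_distribution(sphere_r12, bin_width=0.1)
        q = sphere_r12_profile.q
        qr = np.outer(q, pr.r)
        recon = sphere_r12.n_atoms + 2.0 * (pr.p * np.sinc(qr / np.pi)).sum(axis=1)
        assert np.max(np.abs(recon - sphere_r12_profile.intensity)
                      / sphere_r12_profile.intensity[0]) < 0.01


class TestTransforms:
    def test_kratky_of_inverse_square_is_constant(self):
        q = np.linspace(0.05, 0.5, 40)
        k = kratky_transform(ScatteringProfile(q, 1.0 / q ** 2))
        assert np.allclose(k.intensity, 1.0)

    def test_porod_of_inverse_quartic_is_constant(self):
        q = np.linspace(0.05, 0.5, 40)
        p = porod_transform(ScatteringProfile(q, 1.0 / q ** 4))
        assert np.allclose(p.intensity, 1.0)

    def test_kratky_peak_of_gaussian_at_sqrt3_over_rg(self):
        rg = 16.7
        q = np.linspace(0.001, 0.3, 3000)
        k = kratky_transform(gaussian_profile(rg, q=q))
        q_peak = q[np.argmax(k.intensity)]
        assert abs(q_peak - np.sqrt(3.0) / rg) < 2e-4


class TestRgFromCoords:
    def test_single_atom_zero(self):
        m = analytic_shape("two_points", d=4.0).subset(np.array([True, False]))
        assert rg_from_coords(m) == 0.0

    def test_two_unit_masses_half_distance(self):
        m = analytic_shape("two_points", d=8.0)
        assert np.isclose(rg_from_coords(m, weights="unit"), 4.0)

    def test_weighting_changes_result(self, ideal_micelle):
        u = rg_from_coords(ideal_micelle, weights="unit")
        e = rg_from_coords(ideal_micelle)  # electron weights
        assert u != e
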