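"""Smectic mechanics: closed forms, Gaussian sampler, kinematic scattering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamella.constants import K_B
from lamella.braggsheet import (
    SheetFixture,
    _default_form_profile,
    _mode_stiffness,
    _radial_bins,
    caille_parameter,
    degennes_parameter,
    fit_mechanics,
    invert_mechanics,
    kinematic_bragg_sheets,
    sample_smectic_stack,
    sheet_observables,
    simulate_sheets,
    stack_variance_oracle,
)
from lamella.datamodel import SmecticMechanics

T_REF = 323.15
KT = K_B * T_REF


def mech(kappa_kbt, b_mpa, d=60.0, temperature=T_REF):
    return SmecticMechanics(
        d=d, temperature=temperature,
        kappa=kappa_kbt * K_B * temperature, b_mod=b_mpa * 1e6,
    )


class TestClosedForms:
    def test_caille_reference_value(self):
        # κ = 14 k_BT, B = 29 MPa, d = 50 Å, T = 323.15 K → η ≈ 0.0147
        eta = caille_parameter(14 * KT, 29e6, 50.0, T_REF)
        assert eta == pytest.approx(0.01473, abs=2e-5)

    def test_caille_linear_in_temperature(self):
        e1 = caille_parameter(14 * KT, 29e6, 50.0, 300.0)
        e2 = caille_parameter(14 * KT, 29e6, 50.0, 600.0)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_caille_inverse_sqrt_scaling(self):
        # η ∝ (κB)^(-1/2): quadrupling both moduli quarters η
        e1 = caille_parameter(14 * KT, 29e6, 50.0, T_REF)
        e2 = caille_parameter(4 * 14 * KT, 4 * 29e6, 50.0, T_REF)
        assert e2 == pytest.approx(e1 / 4, rel=1e-12)

    def test_degennes_reference_value(self):
        # Λ = sqrt(κ/(Bd)) ≈ 6.56 Å at the DPPC mechanics
        lam = degennes_parameter(14 * KT, 29e6, 50.0)
        assert lam == pytest.approx(6.563, abs=2e-3)

    def test_degennes_scalings(self):
        lam = degennes_parameter(14 * KT, 29e6, 50.0)
        assert degennes_parameter(4 * 14 * KT, 29e6, 50.0) == pytest.approx(
            2 * lam, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kappa_kbt,b_mpa,d", [(14.0, 29.0, 50.0), (22.0, 1.5, 60.0)]
    )
    def test_forward_inverse_identity_at_reported_mechanics(
        self, kappa_kbt, b_mpa, d
    ):
        kappa, b = kappa_kbt * KT, b_mpa * 1e6
        eta = caille_parameter(kappa, b, d, T_REF)
        lam = degennes_parameter(kappa, b, d)
        k2, b2 = invert_mechanics(eta, lam, d, T_REF)
        assert k2 == pytest.approx(kappa, rel=1e-12)
        assert b2 == pytest.approx(b, rel=1e-12)

    def test_eta_inverse_proportionality(self):
        k1, b1 = invert_mechanics(0.02, 10.0, 55.0, T_REF)
        k2, b2 = invert_mechanics(0.04, 10.0, 55.0, T_REF)
        assert k2 == pytest.approx(k1 / 2, rel=1e-12)
        assert b2 == pytest.approx(b1 / 2, rel=1e-12)

    @given(
        log_kappa=st.floats(min_value=np.log(2), max_value=np.log(60)),
        log_b=st.floats(min_value=np.log(0.1), max_value=np.log(100)),
        d=st.floats(min_value=40.0, max_value=80.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_identity_property_log_uniform(self, log_kappa, log_b, d):
        kappa = np.exp(log_kappa) * KT
        b = np.exp(log_b) * 1e6
        eta = caille_parameter(kappa, b, d, T_REF)
        lam = degennes_parameter(kappa, b, d)
        k2, b2 = invert_mechanics(eta, lam, d, T_REF)
        assert k2 == pytest.approx(kappa, rel=1e-10)
        assert b2 == pytest.approx(b, rel=1e-10)


class TestSampler:
    def test_variance_matches_direct_eigen_sum(self):
        m = mech(22.0, 1.5)
        oracle = stack_variance_oracle(m, 4, 80.0, 8)
        n_seeds = 200
        var = np.zeros(4)
        for s in range(n_seeds):
            f = sample_smectic_stack(4, 80.0, 8, m, seed=s)
            var += (f.u**2).mean(axis=(1, 2))
        var /= n_seeds
        # per-seed spread of the mean-square sets the Monte-Carlo error
        se = oracle * np.sqrt(2.0 / n_seeds) * 3  # generous per-layer bound
        assert np.all(np.abs(var - oracle) < np.maximum(2 * se, 0.3))
        assert var.mean() == pytest.approx(oracle.mean(), rel=0.1)

    def test_low_temperature_limit_freezes(self):
        cold = SmecticMechanics(
            d=60.0, temperature=1e-6, kappa=22 * KT, b_mod=1.5e6
        )
        f = sample_smectic_stack(8, 160.0, 16, cold, seed=0)
        assert np.max(np.abs(f.u)) < 1e-3

    def test_equipartition_per_mode(self):
        """Sampled eigenmode amplitudes carry k_BT/eigenvalue variance."""
        m = mech(22.0, 1.5)
        n_layers, grid, lsz = 4, 8, 80.0
        vecs, stiff, _ = _mode_stiffness(m, n_layers, lsz, grid)
        a_m = (lsz / grid) * 1e-10
        n_seeds = 400
        acc = np.zeros_like(stiff)
        for s in range(n_seeds):
            f = sample_smectic_stack(n_layers, lsz, grid, m, seed=s)
            phi = np.tensordot(vecs.T, f.u * 1e-10, axes=(1, 0))
            c = np.fft.fft2(phi, axes=(-2, -1))
            acc += np.abs(c) ** 2
        acc /= n_seeds
        # DFT coefficients of the unit-normalized fft2: |C|² = M²·kT/(a²E)
        expect = np.where(
            np.isfinite(stiff),
            grid**2 * K_B * m.temperature / (a_m**2 * stiff),
            0.0,
        )
        finite = np.isfinite(stiff) & (expect > 0)
        ratio = acc[finite] / expect[finite]
        # each mode's mean square over n_seeds ~ χ²: 5σ per-mode window
        assert np.all(np.abs(ratio - 1) < 5 * np.sqrt(2.0 / n_seeds) + 0.15)
        assert acc[~finite].max() < 1e-30  # pinned modes stay silent

    def test_interlayer_fluctuation_decreases_with_compression(self):
        diffs = []
        for b_mpa in (0.5, 2.0, 8.0):
            m = mech(22.0, b_mpa)
            vals = []
            for s in range(20):
                f = sample_smectic_stack(8, 160.0, 16, m, seed=s)
                du = np.roll(f.u, -1, axis=0) - f.u
                vals.append((du**2).mean())
            diffs.append(np.mean(vals))
        assert diffs[0] > diffs[1] > diffs[2]

    def test_pinned_boundary_supported(self):
        m = mech(22.0, 1.5)
        f = sample_smectic_stack(8, 160.0, 16, m, seed=1, boundary="pinned")
        assert f.u.shape == (8, 16, 16)


class TestScattering:
    def test_frozen_stack_is_specular_only(self):
        cold = SmecticMechanics(
            d=60.0, temperature=1e-8, kappa=22 * KT, b_mod=1.5e6
        )
        fields = [sample_smectic_stack(8, 160.0, 16, cold, seed=s) for s in range(3)]
        maps = kinematic_bragg_sheets(fields, _default_form_profile(60.0))
        for m in maps:
            off = m.intensity.sum() - m.specular
            assert off < 1e-9 * m.specular

    def test_total_intensity_conserved_as_temperature_varies(self):
        """Fluctuations redistribute specular into diffuse; the form-factor
        weighted total over the sheet zone is conserved."""
        totals = []
        fp = _default_form_profile(60.0)
        for temp in (250.0, 323.15, 400.0):
            m = SmecticMechanics(d=60.0, temperature=temp, kappa=22 * KT, b_mod=1.5e6)
            fields = [
                sample_smectic_stack(8, 160.0, 16, m, seed=s) for s in range(40)
            ]
            maps = kinematic_bragg_sheets(fields, fp, sheets=(1,))
            _, counts, _ = _radial_bins(160.0, 16)
            totals.append((maps[0].intensity * counts[None, :]).sum())
        totals = np.array(totals)
        assert np.ptp(totals) / totals.mean() < 0.01

    def test_diffuse_grows_with_caille_parameter(self):
        """Hotter stacks (larger η at fixed Λ) scatter relatively more
        diffusely on the second sheet."""
        ratios = []
        fp = _default_form_profile(60.0)
        fix = SheetFixture(n_layers=8, grid_points=32, lateral_size=320.0, n_avg=60)
        for temp in (200.0, 323.15, 500.0):
            m = SmecticMechanics(d=60.0, temperature=temp, kappa=22 * KT, b_mod=1.5e6)
            m1, m2 = simulate_sheets(m, fp, fix, seed=3)
            ratio2, _ = sheet_observables(m1, m2)
            ratios.append(1.0 / ratio2)  # diffuse/specular
        assert ratios[0] < ratios[1] < ratios[2]

    def test_larger_penetration_length_slows_first_sheet_decay(self):
        """Doubling Λ at fixed η pushes the bending/compression crossover
        to smaller q_∥, slowing the integrated first-sheet decay."""
        fp = _default_form_profile(60.0)
        fix = SheetFixture(n_layers=8, grid_points=32, lateral_size=320.0, n_avg=60)
        decays = []
        for lam in (16.0, 32.0, 64.0):
            kappa, b = invert_mechanics(0.04, lam, 60.0, T_REF)
            m = SmecticMechanics(d=60.0, temperature=T_REF, kappa=kappa, b_mod=b)
            m1, m2 = simulate_sheets(m, fp, fix, seed=5)
            _, decay = sheet_observables(m1, m2, n_decay=8)
            decays.append(decay[4])
        assert decays[0] > decays[1] > decays[2]

    def test_sheet_index_validation(self):
        m = mech(22.0, 1.5)
        f = sample_smectic_stack(4, 80.0, 8, m, seed=0)
        with pytest.raises(ValueError, match="sheets 1 and 2"):
            kinematic_bragg_sheets([f], _default_form_profile(60.0), sheets=(3,))

    def test_finite_lateral_cutoff_damps_cross_terms(self):
        m = mech(22.0, 1.5)
        fields = [sample_smectic_stack(8, 160.0, 16, m, seed=s) for s in range(10)]
        fp = _default_form_profile(60.0)
        m_inf = kinematic_bragg_sheets(fields, fp, sheets=(1,), r_cutoff=np.inf)[0]
        m_cut = kinematic_bragg_sheets(fields, fp, sheets=(1,), r_cutoff=20.0)[0]
        assert m_cut.specular < m_inf.specular  # coherence reduced
        assert m_cut.intensity.min() >= 0.0


class TestFitMechanics:
    def test_swapped_sheet_roles_rejected(self):
        m = mech(22.0, 1.5)
        fix = SheetFixture(n_layers=4, grid_points=8, lateral_size=80.0, n_avg=4)
        m1, m2 = simulate_sheets(m, _default_form_profile(60.0), fix, seed=0)
        with pytest.raises(ValueError, match="sheet indices"):
            fit_mechanics(m2, m1, d=60.0, temperature=T_REF)

    def test_scaled_down_closed_loop_recovery(self):
        """On a quarter-size fixture the fit recovers the generator η and Λ
        to well within the fixture's Monte-Carlo resolution."""
        fix = SheetFixture(n_layers=8, grid_points=32, lateral_size=320.0, n_avg=80)
        truth = mech(22.0, 1.5)
        maps = simulate_sheets(truth, _default_form_profile(60.0), fix, seed=9)
        fitted, info = fit_mechanics(
            maps[0], maps[1], d=60.0, temperature=T_REF,
            fixture=fix, fit_n_avg=64, n_grid=5,
        )
        eta_t = caille_parameter(truth.kappa, truth.b_mod, 60.0, T_REF)
        lam_t = degennes_parameter(truth.kappa, truth.b_mod, 60.0)
        assert fitted.eta == pytest.approx(eta_t, rel=0.30)
        assert fitted.lambda_dg == pytest.approx(lam_t, rel=0.30)
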