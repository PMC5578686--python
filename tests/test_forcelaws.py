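"""Unit tests for the generalized Lennard-Jones force laws and pore-lock."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msclgate.forcelaws import (
    BELTS,
    InteractionCurve,
    InteractionForceLaw,
    RegularizedLaw,
    apply_reduction,
    build_porelock,
    fit_force_law,
    lj_energy,
    lj_force,
    peak_attractive_force,
    peak_to_peak_reduction,
)
from msclgate.synth import SyntheticDefaults, gen_geometry
from msclgate.units import PN_PER_KCAL_MOL_A


def make_curve(A, B, m=13.0, n=7.0, n_points=50, noise_sd=0.0, seed=0):
    law = InteractionForceLaw(A, B, m, n)
    r_eq = law.r_eq
    r = np.linspace(0.8 * r_eq, 3.0 * r_eq, n_points)
    f = np.asarray(lj_force(law, r))
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0, noise_sd, r.size)
    return InteractionCurve(pair="test", genotype="WT", distances=r, forces=f)


class TestEnergyForce:
    def test_direct_substitution(self):
        law = InteractionForceLaw(A=1.0, B=2.0)
        assert lj_energy(law, 1.0) == pytest.approx(-1.0)

    def test_well_depth_and_location(self):
        # depth B²/(4A) at r_eq = (2A/B)^(1/6)
        law = InteractionForceLaw(A=2.0, B=4.0)
        assert law.r_eq == pytest.approx(1.0)
        assert lj_energy(law, law.r_eq) == pytest.approx(-2.0)
        assert law.well_depth == pytest.approx(2.0)

    def test_long_range_decay(self):
        law = InteractionForceLaw(A=1.0, B=2.0)
        assert abs(lj_energy(law, 100.0)) < 1e-10

    def test_zero_force_at_unit_req(self):
        law = InteractionForceLaw(A=1.0, B=2.0)
        assert lj_force(law, 1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("A,B", [(1.0, 2.0), (3.0, 5.0), (0.7, 4.1)])
    def test_zero_force_at_equilibrium(self, A, B):
        law = InteractionForceLaw(A=A, B=B)
        r_eq = (2.0 * A / B) ** (1.0 / 6.0)
        assert lj_force(law, r_eq) == pytest.approx(0.0, abs=1e-9 * A)

    def test_force_is_negative_energy_gradient(self):
        """F = -dE/dr against a central finite difference, 1e-6 relative."""
        law = InteractionForceLaw(A=1.0, B=2.0)
        for r in (0.9, 1.0, 1.2, 1.5, 2.5):
            h = 1e-6 * r
            fd = -(lj_energy(law, r + h) - lj_energy(law, r - h)) / (2 * h)
            f = lj_force(law, r) / PN_PER_KCAL_MOL_A
            assert f == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_energy_rejects_nonstandard_exponents(self):
        law = InteractionForceLaw(A=1.0, B=2.0, m=15.0, n=8.0)
        with pytest.raises(ValueError, match="13, 7"):
            lj_energy(law, 1.0)

    def test_nonpositive_distance_rejected(self):
        law = InteractionForceLaw(A=1.0, B=2.0)
        with pytest.raises(ValueError):
            lj_energy(law, 0.0)
        with pytest.raises(ValueError):
            lj_force(law, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            InteractionForceLaw(A=-1.0, B=2.0)
        with pytest.raises(ValueError):
            InteractionForceLaw(A=1.0, B=2.0, m=7.0, n=13.0)


class TestFit:
    def test_fixed_fit_recovers_noiseless_parameters(self):
        curve = make_curve(3.0, 5.0)
        law, diag = fit_force_law(curve, fix_exponents=True)
        assert law.A == pytest.approx(3.0, rel=1e-6)
        assert law.B == pytest.approx(5.0, rel=1e-6)
        assert diag.sse < 1e-12

    def test_free_fit_recovers_generalized_exponents(self):
        curve = make_curve(3.0, 5.0, m=15.0, n=8.0)
        law, diag = fit_force_law(curve, fix_exponents=False)
        assert law.m == pytest.approx(15.0, rel=1e-4)
        assert law.n == pytest.approx(8.0, rel=1e-4)
        assert law.A == pytest.approx(3.0, rel=1e-3)
        assert law.B == pytest.approx(5.0, rel=1e-3)

    def test_free_fit_never_worse_than_fixed(self):
        curve = make_curve(3.0, 5.0, noise_sd=5.0, seed=1)
        _, diag_fixed = fit_force_law(curve, fix_exponents=True)
        _, diag_free = fit_force_law(curve, fix_exponents=False)
        assert diag_free.sse <= diag_fixed.sse * (1 + 1e-9)

    def test_noisy_recovery_monte_carlo(self):
        """Median relative error in B under 5% force noise stays below 5%."""
        law0 = InteractionForceLaw(3.0, 5.0)
        peak = peak_attractive_force(law0)
        errs = []
        for seed in range(100):
            curve = make_curve(3.0, 5.0, noise_sd=0.05 * peak, seed=seed)
            law, _ = fit_force_law(curve, fix_exponents=True)
            errs.append(abs(law.B - 5.0) / 5.0)
        assert np.median(errs) < 0.05

    def test_too_few_samples_rejected(self):
        law = InteractionForceLaw(3.0, 5.0)
        r = np.linspace(0.9, 2.0, 4)
        curve = InteractionCurve("p", "WT", r, forces=np.asarray(lj_force(law, r)))
        with pytest.raises(ValueError, match="at least"):
            fit_force_law(curve)

    def test_nonfinite_samples_rejected(self):
        r = np.linspace(0.9, 2.0, 10)
        f = np.ones(10)
        f[3] = np.nan
        curve = InteractionCurve("p", "WT", r, forces=f)
        with pytest.raises(ValueError, match="non-finite"):
            fit_force_law(curve)

    def test_energy_only_curve_is_fittable(self):
        law0 = InteractionForceLaw(3.0, 5.0)
        r = np.linspace(0.9 * law0.r_eq, 3.0 * law0.r_eq, 200)
        curve = InteractionCurve("p", "WT", r, energies=np.asarray(lj_energy(law0, r)))
        law, _ = fit_force_law(curve, fix_exponents=True)
        # numerical differentiation limits the attainable accuracy
        assert law.B == pytest.approx(5.0, rel=0.05)


class TestPeakToPeak:
    def test_identical_curves_give_zero(self):
        c = make_curve(3.0, 5.0)
        c = InteractionCurve("p", "WT", c.distances, energies=np.asarray(
            lj_energy(InteractionForceLaw(3.0, 5.0), c.distances)))
        assert peak_to_peak_reduction(c, c) == pytest.approx(0.0)

    def test_scaled_curve_gives_fifty_percent(self):
        law = InteractionForceLaw(3.0, 5.0)
        r = np.linspace(0.9, 3.0, 60)
        e = np.asarray(lj_energy(law, r))
        wt = InteractionCurve("p", "WT", r, energies=e)
        mut = InteractionCurve("p", "G22N", r, energies=0.5 * e)
        assert peak_to_peak_reduction(wt, mut) == pytest.approx(50.0)

    def test_zero_wt_depth_rejected(self):
        r = np.linspace(1.0, 2.0, 10)
        flat = InteractionCurve("p", "WT", r, energies=np.zeros(10))
        with pytest.raises(ValueError, match="depth"):
            peak_to_peak_reduction(flat, flat)


class TestReduction:
    def test_zero_reduction_is_identity(self):
        law = InteractionForceLaw(3.0, 5.0)
        out = apply_reduction(law, 0.0)
        assert out.A == law.A and out.B == law.B

    def test_half_reduction_halves_depth_preserves_req(self):
        law = InteractionForceLaw(3.0, 5.0)
        out = apply_reduction(law, 0.5)
        assert out.well_depth == pytest.approx(0.5 * law.well_depth, rel=1e-12)
        assert out.r_eq == pytest.approx(law.r_eq, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_reduction(InteractionForceLaw(1.0, 2.0), 1.5)

    @given(rho=st.floats(0.0, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_reduction_commutes_with_fitting(self, rho):
        """fit(scale(samples)) == scale(fit(samples)) on noiseless data."""
        curve = make_curve(3.0, 5.0)
        scaled = InteractionCurve(
            curve.pair, curve.genotype, curve.distances, forces=(1 - rho) * curve.forces
        )
        law_then_scale = apply_reduction(fit_force_law(curve)[0], rho)
        scale_then_law, _ = fit_force_law(scaled)
        assert scale_then_law.A == pytest.approx(law_then_scale.A, rel=1e-6, abs=1e-12)
        assert scale_then_law.B == pytest.approx(law_then_scale.B, rel=1e-6, abs=1e-12)


class TestPorelock:
    def test_wild_type_has_25_connectors(self, defaults):
        cons = build_porelock(gen_geometry(), defaults.wt_laws())
        assert len(cons) == 25

    def test_g26_deletion_leaves_20(self, defaults):
        cons = build_porelock(gen_geometry(), defaults.wt_laws(), deletions={"V23-G26"})
        assert len(cons) == 20
        assert "V23-G26" not in cons.belts_present()

    def test_all_belts_deleted_leaves_none(self, defaults):
        cons = build_porelock(gen_geometry(), defaults.wt_laws(), deletions=set(BELTS))
        assert len(cons) == 0

    @given(dels=st.sets(st.sampled_from(BELTS)))
    @settings(max_examples=20, deadline=None)
    def test_connector_count_formula(self, dels):
        defaults = SyntheticDefaults()
        cons = build_porelock(gen_geometry(), defaults.wt_laws(), deletions=dels)
        assert len(cons) == 5 * (5 - len(dels))

    def test_unknown_deletion_rejected(self, defaults):
        with pytest.raises(ValueError, match="unknown belt"):
            build_porelock(gen_geometry(), defaults.wt_laws(), deletions={"X1-Y2"})

    def test_missing_law_rejected(self, defaults):
        laws = defaults.wt_laws()
        del laws["L19-L19"]
        with pytest.raises(ValueError, match="L19-L19"):
            build_porelock(gen_geometry(), laws)


class TestRegularizedLaw:
    def test_cap_is_ten_times_peak_attraction(self):
        law = InteractionForceLaw.from_well(2.0, 6.0)
        reg = RegularizedLaw.from_law(law)
        assert reg.f_cap == pytest.approx(10.0 * peak_attractive_force(law))
        # continuity at the cap radius
        e_lo, f_lo = reg.energy_force(reg.r_cap - 1e-9)
        e_hi, f_hi = reg.energy_force(reg.r_cap + 1e-9)
        assert e_lo == pytest.approx(e_hi, rel=1e-4, abs=1e-5)
        assert f_lo == pytest.approx(f_hi, rel=1e-4)

    def test_interaction_vanishes_beyond_cutoff(self):
        law = InteractionForceLaw.from_well(2.0, 6.0)
        reg = RegularizedLaw.from_law(law)
        e, f = reg.energy_force(reg.r_cut + 0.1)
        assert e == 0.0 and f == 0.0

    def test_taper_force_matches_energy_gradient(self):
        law = InteractionForceLaw.from_well(2.0, 6.0)
        reg = RegularizedLaw.from_law(law)
        for r in np.linspace(reg.r_switch + 0.01, reg.r_cut - 0.01, 7):
            h = 1e-6
            e1, _ = reg.energy_force(r - h)
            e2, _ = reg.energy_force(r + h)
            _, f = reg.energy_force(r)
            assert f == pytest.approx(-(e2 - e1) / (2 * h), rel=1e-4, abs=1e-8)
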