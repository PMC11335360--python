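"""Rotation theorem, verticalization, plans, and model-guided optimization."""

import numpy as np
import pandas as pd
import pytest

from svdecon import (
    RotationPlan,
    RotationStep,
    apply_plan,
    as_rotated,
    assemble_matrix,
    decompose,
    gen_two_state,
    invariance_report,
    optimize_to_model,
    rotate_pair,
    verticalize,
)
from svdecon.core_data import MetadataTable
from svdecon.rotation import AmbiguousRotationError
from svdecon.svd_engine import CoefficientSet


def _cs(c):
    c = np.asarray(c, dtype=float)
    meta = MetadataTable(pd.DataFrame({"t": np.arange(c.shape[1], dtype=float)}),
                         ordering_axis="t")
    return CoefficientSet(c, meta)


class TestRotatePair:
    def test_zero_angle_is_identity(self, random_basis):
        out = rotate_pair(random_basis, 1, 2, 0.0)
        assert np.allclose(out.r, random_basis.r, atol=0)
        assert np.allclose(out.f, random_basis.f, atol=0)

    def test_ninety_degrees_swaps_dimensions(self, random_basis):
        out = rotate_pair(random_basis, 1, 2, 90.0)
        # R1' = -U2, R2' = U1 within float trig error
        assert np.allclose(out.r[:, 0], -random_basis.r[:, 1], atol=1e-12)
        assert np.allclose(out.r[:, 1], random_basis.r[:, 0], atol=1e-12)

    def test_reconstruction_invariance_random_angles(self, random_basis, rng):
        work = random_basis.copy()
        for _ in range(10):
            h, k = sorted(rng.choice(np.arange(1, 5), size=2, replace=False))
            work = rotate_pair(work, int(h), int(k), float(rng.uniform(-180, 180)))
        assert invariance_report(random_basis, work) < 1e-12

    def test_rotation_then_inverse_restores(self, random_basis):
        out = rotate_pair(rotate_pair(random_basis, 2, 4, 33.3), 2, 4, -33.3)
        assert np.allclose(out.r, random_basis.r, atol=1e-12)
        assert np.allclose(out.f, random_basis.f, atol=1e-12)

    def test_orthonormality_preserved(self, random_basis):
        out = rotate_pair(random_basis, 1, 3, 47.0)
        assert np.allclose(out.r.T @ out.r, np.eye(out.n_dims), atol=1e-10)

    def test_total_energy_preserved(self, random_basis):
        out = rotate_pair(random_basis, 1, 2, -61.0)
        assert np.isclose(np.sum(out.f**2), np.sum(random_basis.f**2), rtol=1e-12)

    def test_pairwise_point_distances_preserved(self, random_basis):
        before = random_basis.f
        after = rotate_pair(random_basis, 1, 4, 28.0).f
        db = np.linalg.norm(before[:, :, None] - before[:, None, :], axis=0)
        da = np.linalg.norm(after[:, :, None] - after[:, None, :], axis=0)
        assert np.allclose(db, da, atol=1e-10)

    def test_untouched_dimensions_unchanged(self, random_basis):
        out = rotate_pair(random_basis, 1, 2, 30.0)
        assert np.array_equal(out.r[:, 2], random_basis.r[:, 2])
        assert np.array_equal(out.f[3], random_basis.f[3])

    def test_invalid_pairs_rejected(self, random_basis):
        with pytest.raises(ValueError):
            rotate_pair(random_basis, 2, 2, 10.0)
        with pytest.raises(ValueError):
            rotate_pair(random_basis, 3, 1, 10.0)
        with pytest.raises(IndexError):
            rotate_pair(random_basis, 1, 9, 10.0)

    def test_rotations_do_not_commute(self, random_basis):
        ab = rotate_pair(rotate_pair(random_basis, 1, 2, 50.0), 2, 3, 40.0)
        ba = rotate_pair(rotate_pair(random_basis, 2, 3, 40.0), 1, 2, 50.0)
        assert not np.allclose(ab.r, ba.r, atol=1e-6)
        # yet both are valid rotations of the same subspace
        assert invariance_report(ab, ba) < 1e-12


class TestRotationPlan:
    def test_two_step_plan_reconstruction_invariant(self, random_basis):
        # a plan shaped like a published two-step deconvolution: rotate the
        # (2,3) plane by -43.8 deg then the (1,3) plane by 54.1 deg
        plan = RotationPlan([RotationStep(2, 3, -43.8), RotationStep(1, 3, 54.1)], 4)
        out = apply_plan(random_basis, plan)
        assert invariance_report(random_basis, out) < 1e-10
        assert len(out.history) == 2

    def test_inverse_plan_round_trips(self, random_basis):
        plan = RotationPlan([RotationStep(1, 2, 17.0), RotationStep(2, 4, -80.0),
                             RotationStep(3, 4, 5.5)], 4)
        back = apply_plan(apply_plan(random_basis, plan), plan.inverse())
        assert np.allclose(back.r, random_basis.r, atol=1e-12)
        assert np.allclose(back.f, random_basis.f, atol=1e-12)

    def test_json_round_trip(self):
        plan = RotationPlan([RotationStep(1, 3, -12.25), RotationStep(2, 3, 88.0)], 3)
        back = RotationPlan.from_json(plan.to_json())
        assert back.n_dims == 3
        assert [(s.h, s.k, s.theta_deg) for s in back] == \
               [(s.h, s.k, s.theta_deg) for s in plan]

    def test_step_validation(self):
        with pytest.raises(ValueError):
            RotationStep(3, 2, 10.0)
        with pytest.raises(ValueError):
            RotationStep(0, 2, 10.0)
        with pytest.raises(ValueError):
            RotationStep(1, 1, 10.0)
        with pytest.raises(ValueError):
            RotationStep(1, 2, float("nan"))
        with pytest.raises(ValueError):
            RotationPlan([RotationStep(1, 5, 10.0)], n_dims=3)


class TestVerticalize:
    def test_slope_one_gives_45_degrees(self):
        x = np.linspace(0.0, 1.0, 20)
        cs = _cs(np.vstack([x, x]))
        assert np.isclose(verticalize(cs, 1, 2), 45.0, atol=1e-9)

    def test_already_vertical_gives_zero(self):
        y = np.linspace(-1.0, 2.0, 15)
        cs = _cs(np.vstack([np.full(15, 0.7), y]))
        assert np.isclose(verticalize(cs, 1, 2), 0.0, atol=1e-9)

    def test_collinear_trajectory_flattens_exactly(self, rng):
        # arbitrary line through arbitrary offset
        s = rng.normal(size=30)
        c = np.vstack([0.3 + 0.8 * s, -1.1 + 1.7 * s])
        cs = _cs(c)
        theta = verticalize(cs, 1, 2)
        th = np.radians(theta)
        f1 = c[0] * np.cos(th) - c[1] * np.sin(th)
        f2 = c[0] * np.sin(th) + c[1] * np.cos(th)
        assert np.var(f1) / np.var(f2) < 1e-12

    def test_two_state_regime_noise_free(self, two_state_clean):
        series, truth = two_state_clean
        trip = decompose(assemble_matrix(series))
        basis = as_rotated(trip, 2)
        theta = verticalize(basis, 1, 2)
        rotated = rotate_pair(basis, 1, 2, theta)
        f1, f2 = rotated.f
        assert np.var(f1) / np.var(f2) < 1e-6
        # one rotated component is proportional to the pure start-state spectrum
        a = truth["pure_a"]
        corr = abs(np.corrcoef(rotated.r[:, 0], a)[0, 1])
        assert corr > 0.999999

    def test_isotropic_scatter_raises(self, rng):
        # points on a circle: no preferred direction
        ang = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
        cs = _cs(np.vstack([np.cos(ang), np.sin(ang)]))
        with pytest.raises(AmbiguousRotationError):
            verticalize(cs, 1, 2)

    def test_coincident_points_raise(self):
        cs = _cs(np.vstack([np.full(5, 1.0), np.full(5, -2.0)]))
        with pytest.raises(AmbiguousRotationError):
            verticalize(cs, 1, 2)

    def test_angle_in_open_closed_range(self, rng):
        for _ in range(20):
            c = rng.normal(size=(2, 12))
            theta = verticalize(_cs(c), 1, 2)
            assert -90.0 < theta <= 90.0


class TestInvarianceReport:
    def test_detects_inconsistent_transformation(self, random_basis):
        broken = random_basis.copy()
        # rotate components but not coefficients: not a valid rotation
        th = np.radians(30.0)
        r1, r2 = broken.r[:, 0].copy(), broken.r[:, 1].copy()
        broken.r[:, 0] = r1 * np.cos(th) - r2 * np.sin(th)
        broken.r[:, 1] = r1 * np.sin(th) + r2 * np.cos(th)
        assert invariance_report(random_basis, broken) > 1e-3

    def test_dimension_mismatch_rejected(self, random_basis, two_state_basis):
        with pytest.raises(ValueError):
            invariance_report(random_basis, as_rotated(two_state_basis))


class TestOptimizeToModel:
    def test_identity_when_target_already_kinetic(self):
        # build a basis whose dim-2 coefficient is already a clean exponential
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 10.0, 60)
        u, _ = np.linalg.qr(rng.normal(size=(40, 2)))
        f = np.vstack([np.full(60, 2.0), 1.0 - np.exp(-t / 2.0)])
        meta = MetadataTable(pd.DataFrame({"t": t}), ordering_axis="t")
        from svdecon.core_data import RowAddressing
        from svdecon.rotation import RotatedBasis
        basis = RotatedBasis(u, f, RowAddressing(wavelengths=np.arange(40.0)), meta)
        plan, fit = optimize_to_model(basis, target_dim=2, model="single_exp")
        assert all(abs(s.theta_deg) < 1e-6 for s in plan)
        assert np.isclose(fit.model.tau, 2.0, rtol=1e-6)

    def test_improves_objective_on_mixed_basis(self, two_state_basis):
        basis = as_rotated(two_state_basis, 2)
        t = basis.metadata.axis_values()
        from svdecon.kinetics import fit_single_exp
        rss_before = fit_single_exp(t, basis.f[1]).rss
        plan, fit = optimize_to_model(basis, target_dim=2, model="single_exp")
        assert fit.rss <= rss_before + 1e-15
        out = apply_plan(basis, plan)
        assert invariance_report(basis, out) < 1e-10

    def test_invalid_dimensions_rejected(self, random_basis):
        with pytest.raises(ValueError):
            optimize_to_model(random_basis, target_dim=9)
        with pytest.raises(ValueError):
            optimize_to_model(random_basis, target_dim=1, search_dims=[1])
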