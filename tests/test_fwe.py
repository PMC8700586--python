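import numpy as np
import pytest

from fwdti import (
    DWIVolume,
    FitConfig,
    fit_fwe,
    fwe_objective,
    init_fw_fit,
    predict_signal,
    tensor_from_fa_md,
)
from fwdti.dti import eigenvalues_field, fa_from_eigenvalues, fit_dti, matrix_to_tensor6
from fwdti.fwe import D_FW, DegeneracyError, _Objective, _attenuations
from fwdti.gradients_io import GradientScheme


def _block_dwi(scheme, f, tensor, s0=1000.0, shape=(4, 4, 4)):
    sig = predict_signal(f, tensor, s0, scheme)
    data = np.broadcast_to(sig, shape + (len(scheme),)).copy()
    return DWIVolume(data=data, affine=np.eye(4))


@pytest.fixture(scope="module")
def tissue():
    return tensor_from_fa_md(0.7, 0.7e-3, (1.0, 0.0, 0.0))


class TestInitialization:
    def _f_init_for_abar(self, scheme, a_bar_target, tissue):
        """Build a DWI whose mean b=1000 attenuation equals a_bar_target."""
        cfg = FitConfig()
        data = np.ones((1, 1, 1, len(scheme)))
        data[..., scheme.bvals == 1000] = a_bar_target
        dwi = DWIVolume(data=data, affine=np.eye(4))
        f_init, _, _ = init_fw_fit(dwi, scheme, config=cfg)
        return float(f_init[0, 0, 0])

    def test_water_attenuation_clamps_high(self, scheme, tissue):
        a_w = np.exp(-1000 * D_FW)
        assert self._f_init_for_abar(scheme, a_w, tissue) == pytest.approx(0.99)

    def test_tissue_attenuation_clamps_low(self, scheme, tissue):
        a_t = np.exp(-1000 * 0.6e-3)
        assert self._f_init_for_abar(scheme, a_t, tissue) == pytest.approx(0.01)

    def test_midpoint_attenuation_gives_half(self, scheme, tissue):
        a_mid = (np.exp(-1000 * 0.6e-3) + np.exp(-1000 * D_FW)) / 2
        assert self._f_init_for_abar(scheme, a_mid, tissue) == pytest.approx(0.5, abs=1e-9)

    def test_single_shell_scheme_rejected(self, tissue):
        bvals = np.r_[0.0, np.full(8, 1000.0)]
        from fwdti.gradients_io import DIRECTIONS_8

        scheme1 = GradientScheme(bvals, np.vstack([np.zeros(3), DIRECTIONS_8]))
        dwi = _block_dwi(scheme1, 0.3, tissue)
        with pytest.raises(DegeneracyError):
            init_fw_fit(dwi, scheme1)
        with pytest.raises(DegeneracyError):
            fit_fwe(dwi, scheme1)


class TestObjective:
    def test_zero_at_ground_truth(self, scheme, tissue, small_noiseless):
        spec, dwi, sch, masks, truth = small_noiseless
        cfg = FitConfig(alpha=0.0)
        j = fwe_objective(truth.f_true, truth.tensor_true, dwi, sch, cfg)
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_constant_tensor_field_has_zero_regularizer(self, scheme, tissue):
        dwi = _block_dwi(scheme, 0.3, tissue)
        cfg0 = FitConfig(alpha=0.0)
        cfg1 = FitConfig(alpha=5.0)
        field = np.broadcast_to(
            matrix_to_tensor6(tissue), dwi.shape[:3] + (6,)
        ).copy()
        f = np.full(dwi.shape[:3], 0.3)
        assert fwe_objective(f, field, dwi, scheme, cfg1) == pytest.approx(
            fwe_objective(f, field, dwi, scheme, cfg0)
        )

    def test_two_voxel_regularizer_hand_value(self, scheme, tissue):
        # tensors differing by diag(eps, 0, 0) across one face: reg = alpha*eps^2
        eps = 2.0e-4
        alpha = 3.0
        sig = predict_signal(0.3, tissue, 1.0, scheme)
        data = np.broadcast_to(sig, (2, 1, 1, len(scheme))).copy()
        dwi = DWIVolume(data=data, affine=np.eye(4))
        field = np.zeros((2, 1, 1, 6))
        field[0, 0, 0] = matrix_to_tensor6(tissue)
        field[1, 0, 0] = matrix_to_tensor6(tissue + np.diag([eps, 0.0, 0.0]))
        f = np.full((2, 1, 1), 0.3)
        j0 = fwe_objective(f, field, dwi, scheme, FitConfig(alpha=0.0))
        j1 = fwe_objective(f, field, dwi, scheme, FitConfig(alpha=alpha))
        assert j1 - j0 == pytest.approx(alpha * eps**2, rel=1e-10)


class TestFitRecovery:
    def test_pure_free_water_estimated_to_one(self, scheme):
        iso = tensor_from_fa_md(0.0, 0.6e-3, (1, 0, 0))
        dwi = _block_dwi(scheme, 1.0, iso)
        res = fit_fwe(dwi, scheme, config=FitConfig(alpha=0.0))
        assert np.all(np.abs(res.f[res.fit_mask] - 1.0) <= 0.01)
        assert res.unidentifiable[res.fit_mask].all()

    def test_mixed_voxel_recovery(self, scheme, tissue):
        dwi = _block_dwi(scheme, 0.5, tissue, shape=(2, 2, 2))
        res = fit_fwe(dwi, scheme, config=FitConfig(alpha=0.0))
        assert np.all(np.abs(res.f[res.fit_mask] - 0.5) < 0.02)
        assert np.all(np.abs(res.fat[res.fit_mask] - 0.7) < 0.02)

    def test_objective_monotone_noiseless(self, small_noiseless):
        _, dwi, sch, masks, _ = small_noiseless
        res = fit_fwe(dwi, sch, config=FitConfig(alpha=0.0))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_objective_monotone_noisy_regularized(self, small_noisy):
        _, dwi, sch, masks, _ = small_noisy
        res = fit_fwe(dwi, sch)  # default alpha of the config is 0
        from fwdti.fwe import default_alpha

        res_reg = fit_fwe(dwi, sch, config=FitConfig(alpha=default_alpha(33)))
        for r in (res, res_reg):
            assert np.all(np.diff(r.objective_trace) <= 1e-9)

    def test_fw_free_stripe_fat_matches_dti_fa(self, small_noiseless):
        # on noiseless f=0 voxels the two estimators agree
        _, dwi, sch, masks, truth = small_noiseless
        res = fit_fwe(dwi, sch, config=FitConfig(alpha=0.0))
        tensors, _, dti_mask = fit_dti(dwi, sch, shell=1000.0)
        stripe = masks.brain & (truth.f_true == 0) & dti_mask & res.fit_mask
        assert stripe.sum() > 5
        fa = fa_from_eigenvalues(eigenvalues_field(tensors[stripe]))
        assert np.all(np.abs(res.fat[stripe] - fa) < 0.02)

    def test_scale_invariance(self, scheme, tissue):
        dwi1 = _block_dwi(scheme, 0.4, tissue, shape=(2, 2, 2))
        dwi2 = DWIVolume(data=dwi1.data * 7.3, affine=np.eye(4))
        cfg = FitConfig(alpha=0.0)
        r1 = fit_fwe(dwi1, scheme, config=cfg)
        r2 = fit_fwe(dwi2, scheme, config=cfg)
        np.testing.assert_allclose(r1.f, r2.f, atol=1e-6)
        np.testing.assert_allclose(r1.fat, r2.fat, atol=1e-6)

    def test_fat_not_below_fa_where_fw_present(self, small_noiseless):
        """Removing the isotropic pool can only raise anisotropy (noiseless)."""
        _, dwi, sch, masks, _ = small_noiseless
        res = fit_fwe(dwi, sch, config=FitConfig(alpha=0.0))
        tensors, _, dti_mask = fit_dti(dwi, sch, shell=1000.0)
        sel = res.fit_mask & dti_mask & (res.f > 0.05) & ~res.unidentifiable
        fa = np.full(sel.shape, np.nan)
        fa[sel] = fa_from_eigenvalues(eigenvalues_field(tensors[sel]))
        assert sel.sum() > 100
        assert np.all(res.fat[sel] >= fa[sel] - 1e-6)

    def test_noiseless_phantom_rmse(self, small_noiseless):
        _, dwi, sch, masks, truth = small_noiseless
        res = fit_fwe(dwi, sch, config=FitConfig(alpha=0.0))
        ok = res.fit_mask
        assert np.sqrt(np.mean((res.f[ok] - truth.f_true[ok]) ** 2)) < 0.02
        sel = ok & ~res.unidentifiable & (truth.f_true <= 0.9)
        fat_true = fa_from_eigenvalues(eigenvalues_field(truth.tensor_true[sel]))
        assert np.sqrt(np.mean((res.fat[sel] - fat_true) ** 2)) < 0.02


class TestNumericalPieces:
    def test_closed_form_eigenvalues_match_lapack(self, rng):
        from fwdti.fwe import _eigvals_sym6
        from fwdti.dti import tensor6_to_matrix

        d6 = rng.standard_normal((500, 6))
        lam = _eigvals_sym6(d6)
        ref = np.linalg.eigvalsh(tensor6_to_matrix(d6))
        np.testing.assert_allclose(lam, ref, atol=1e-10)

    def test_projection_respects_bounds(self, rng):
        from fwdti.fwe import _project_eigenvalues

        d6 = rng.standard_normal((200, 6)) * 2.0
        out = _project_eigenvalues(d6, 0.1, 0.9)
        lam = np.linalg.eigvalsh(
            __import__("fwdti.dti", fromlist=["tensor6_to_matrix"]).tensor6_to_matrix(out)
        )
        assert lam.min() >= 0.1 - 1e-9 and lam.max() <= 0.9 + 1e-9

    def test_gradient_matches_finite_differences(self, scheme, tissue, rng):
        cfg = FitConfig(alpha=2.0)
        dwi = _block_dwi(scheme, 0.35, tissue, shape=(2, 2, 1))
        dwi.data *= 1 + 0.01 * rng.standard_normal(dwi.data.shape)
        mask = np.ones(dwi.shape[:3], bool)
        a_obs, _, ok = _attenuations(dwi, scheme, mask)
        obj = _Objective(a_obs, scheme, ok, cfg)
        n = int(ok.sum())
        f = rng.uniform(0.2, 0.6, n)
        dt = (np.broadcast_to(matrix_to_tensor6(tissue) / D_FW, (n, 6))
              + 0.02 * rng.standard_normal((n, 6)))

        def value(fv, dv):
            return float(obj.data_per_voxel(fv, dv).sum()) + obj.reg_total(dv)

        gf, gd, _ = obj.grad(f, dt)
        h = 1e-7
        for v, j in [(0, 0), (1, 3), (3, 5)]:
            dp = dt.copy()
            dp[v, j] += h
            dm = dt.copy()
            dm[v, j] -= h
            num = (value(f, dp) - value(f, dm)) / (2 * h)
            assert gd[v, j] == pytest.approx(num, rel=1e-4, abs=1e-8)
        fp = f.copy(); fp[2] += h
        fm = f.copy(); fm[2] -= h
        num = (value(fp, dt) - value(fm, dt)) / (2 * h)
        assert gf[2] == pytest.approx(num, rel=1e-4, abs=1e-8)
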