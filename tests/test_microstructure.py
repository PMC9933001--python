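import numpy as np
import pytest

from bundlerepro import (
    DWIScheme,
    extract_in_bundle,
    fit_tensor_irwlls,
    simulate_dwi,
    variance_decomposition,
)
from bundlerepro.microstructure import TensorFitError, fa_md_from_eigenvalues
from bundlerepro.synthetic import default_scheme
from bundlerepro.voxelization import BundleMask
from oracles import closed_form_fa

ANISO = np.diag([1.7e-3, 0.3e-3, 0.3e-3])


def _field(D, shape=(4, 4, 4)):
    return np.tile(D, shape + (1, 1))


def test_scheme_validation():
    with pytest.raises(ValueError):
        DWIScheme(np.full(5, 1000.0), np.tile([1.0, 0, 0], (5, 1)))  # no b0
    bvals = np.array([0.0] + [1000.0] * 6)
    bad = np.vstack([[0, 0, 0]] + [[2.0, 0, 0]] * 6)
    with pytest.raises(ValueError):
        DWIScheme(bvals, bad)  # non-unit directions


def test_isotropic_noise_free():
    scheme = default_scheme(30)
    sig = simulate_dwi(_field(np.eye(3) * 1e-3), scheme, snr=None)
    fit = fit_tensor_irwlls(sig, scheme)
    assert np.abs(fit.fa).max() < 1e-9
    assert fit.md == pytest.approx(1e-3, abs=1e-9)


def test_anisotropic_closed_form_fa():
    scheme = default_scheme(32)
    fit = fit_tensor_irwlls(simulate_dwi(_field(ANISO), scheme, snr=None), scheme)
    expected = closed_form_fa([1.7, 0.3, 0.3])
    assert fit.fa[0, 0, 0] == pytest.approx(expected, abs=1e-6)
    assert fit.md[0, 0, 0] == pytest.approx(0.76667e-3, rel=1e-4)


def test_noise_free_recovery_random_tensors(rng):
    """Noise-free IRWLLS recovers arbitrary SPD tensors to 1e-9 relative."""
    scheme = default_scheme(32)
    for _ in range(5):
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        lam = rng.uniform(0.2e-3, 2.0e-3, size=3)
        D = Q @ np.diag(lam) @ Q.T
        fit = fit_tensor_irwlls(simulate_dwi(_field(D, (2, 2, 2)), scheme, snr=None), scheme)
        assert np.abs(fit.tensor[0, 0, 0] - D).max() / np.abs(D).max() < 1e-9


def test_snr30_mean_fa():
    scheme = default_scheme(32)
    field = _field(ANISO, (200, 1, 1))
    sig = simulate_dwi(field, scheme, snr=30, seed=1)
    fit = fit_tensor_irwlls(sig, scheme)
    assert abs(fit.fa.mean() - closed_form_fa([1.7, 0.3, 0.3])) < 0.03


@pytest.mark.parametrize(
    "lam,target_fa",
    [((1.0e-3, 0.57e-3, 0.57e-3), 0.3), ((1.7e-3, 0.3e-3, 0.3e-3), 0.8)],
)
def test_fa_bias_small_at_snr30(lam, target_fa):
    """|bias| < 0.05 for moderate and high anisotropy at SNR 30."""
    scheme = default_scheme(32)
    field = _field(np.diag(lam), (200, 1, 1))
    fit = fit_tensor_irwlls(simulate_dwi(field, scheme, snr=30, seed=2), scheme)
    assert abs(fit.fa.mean() - closed_form_fa(lam)) < 0.05


def test_zero_iterations_equals_ordinary_lls(rng):
    """n_iter=0 reproduces the plain log-linear least-squares fit."""
    scheme = default_scheme(32)
    sig = simulate_dwi(_field(ANISO, (3, 3, 3)), scheme, snr=25, seed=3)
    fit0 = fit_tensor_irwlls(sig, scheme, n_iter=0)
    # independent OLS in log space
    B = scheme.design_matrix()
    y = np.log(sig.reshape(-1, scheme.n_volumes)).T
    theta = np.linalg.lstsq(B, y, rcond=None)[0].T
    d_ols = theta[:, 1:4]
    assert np.allclose(fit0.tensor.reshape(-1, 3, 3)[:, [0, 1, 2], [0, 1, 2]], d_ols, atol=1e-12)


def test_reweighting_changes_noisy_fit():
    scheme = default_scheme(32)
    sig = simulate_dwi(_field(ANISO, (3, 3, 3)), scheme, snr=15, seed=4)
    fit0 = fit_tensor_irwlls(sig, scheme, n_iter=0)
    fit2 = fit_tensor_irwlls(sig, scheme, n_iter=2)
    assert not np.allclose(fit0.tensor, fit2.tensor)


def test_fa_rotation_invariance(rng):
    """FA is invariant to rotating both the tensor and the gradient set."""
    scheme = default_scheme(32)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    D_rot = Q @ ANISO @ Q.T
    scheme_rot = DWIScheme(scheme.bvals, scheme.bvecs @ Q.T)
    fit1 = fit_tensor_irwlls(simulate_dwi(_field(ANISO, (1, 1, 1)), scheme, snr=None), scheme)
    fit2 = fit_tensor_irwlls(simulate_dwi(_field(D_rot, (1, 1, 1)), scheme_rot, snr=None), scheme_rot)
    assert fit1.fa[0, 0, 0] == pytest.approx(fit2.fa[0, 0, 0], abs=1e-6)


def test_eigenvalue_clamping():
    fa, md = fa_md_from_eigenvalues(np.array([[1.0, -0.1, 0.0]]))
    assert 0.0 <= fa[0] <= 1.0
    assert md[0] == pytest.approx(1.0 / 3)


def test_fit_requires_seven_volumes():
    bvals = np.array([0.0] + [1000.0] * 6)
    g = np.array([[0, 0, 0]] + [[1.0, 0, 0]] * 6)  # rank-deficient directions
    scheme = DWIScheme.__new__(DWIScheme)
    scheme.bvals, scheme.bvecs = bvals, g.astype(float)
    with pytest.raises(TensorFitError):
        fit_tensor_irwlls(np.ones((2, 2, 2, 7)), scheme)


def test_extract_in_bundle():
    roi = np.zeros((5, 5, 5), bool)
    roi[1:3, 1:3, 1:3] = True
    mean, n = extract_in_bundle(np.full((5, 5, 5), 0.5), BundleMask(roi, np.eye(4)))
    assert mean == 0.5 and n == 8
    half = np.zeros((5, 5, 5))
    half[1:3, 1:3, 1] = 1.0  # half the roi voxels
    mean, _ = extract_in_bundle(half, BundleMask(roi, np.eye(4)))
    assert mean == pytest.approx(0.5)
    with pytest.raises(ValueError):
        extract_in_bundle(half, BundleMask(np.zeros((5, 5, 5), bool), np.eye(4)))


def test_extract_matches_brute_force(rng):
    metric = rng.random((8, 8, 8))
    roi = np.zeros((8, 8, 8), bool)
    roi.flat[rng.choice(512, 50, replace=False)] = True
    mean, n = extract_in_bundle(metric, BundleMask(roi, np.eye(4)))
    total = sum(metric[i] for i in map(tuple, np.argwhere(roi)))
    assert n == 50 and mean == pytest.approx(total / 50)


def _roi(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return BundleMask(m, np.eye(4))


def test_variance_decomposition_identical_maps():
    """Same maps, different ROIs: fixed-ROI MAPE is exactly zero."""
    shape = (6, 6, 6)
    grad = np.linspace(0.2, 0.8, 6)[:, None, None] * np.ones(shape)
    maps = {"ref": grad, "a": grad.copy()}
    rois = {"ref": _roi(shape, np.s_[1:3]), "a": _roi(shape, np.s_[3:5])}
    out = variance_decomposition(maps, rois, rois["ref"], [("X", "ref", "a")])
    assert out["mape_fixed_roi"].iloc[0] == 0.0
    assert out["mape_native_roi"].iloc[0] >= 0.0


def test_variance_decomposition_identical_rois():
    """Same ROI everywhere: the two MAPE modes coincide."""
    shape = (6, 6, 6)
    grad = np.linspace(0.2, 0.8, 6)[:, None, None] * np.ones(shape)
    maps = {"ref": grad, "a": grad * 1.1}
    roi = _roi(shape, np.s_[2:4])
    out = variance_decomposition(maps, {"ref": roi, "a": roi}, roi, [("X", "ref", "a")])
    assert out["mape_fixed_roi"].iloc[0] == pytest.approx(out["mape_native_roi"].iloc[0])


def test_variance_decomposition_skips_missing():
    out = variance_decomposition({}, {}, _roi((3, 3, 3), np.s_[1]), [("X", "ref", "a")])
    assert out.empty
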