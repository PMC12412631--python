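"""Spatially regularized image reconstruction against dense linear-algebra
oracles and physical separation properties."""

import numpy as np
import pytest

from hdnirs.recon import (
    ImageReconstructor,
    ReconConfig,
    hrf_to_od,
    image_timecourse,
    reconstruct,
    rescale_sensitivity,
    stack_multispectral,
)


def _dense_oracle(y, A, alpha_spatial, alpha_meas):
    """Direct dense evaluation of the regularized inversion (explicit
    inverses; deliberately naive and independent of the implementation)."""
    col = np.diag(A.T @ A)
    lam_sp = alpha_spatial * col.max()
    L = np.diag(np.sqrt(col + lam_sp))
    Linv = np.linalg.inv(L)
    A_hat = A @ Linv
    M = A_hat @ A_hat.T
    lam = alpha_meas * np.diag(M).max()
    return Linv @ A_hat.T @ np.linalg.inv(M + lam * np.eye(M.shape[0])) @ y


class TestRescale:
    def test_identity_closed_form(self):
        A = np.eye(3)
        A_hat, L = rescale_sensitivity(A, alpha_spatial=1.0)
        np.testing.assert_allclose(L, np.sqrt(2.0))
        np.testing.assert_allclose(A_hat, A / np.sqrt(2.0))

    def test_toy_matches_hand_formula(self, rng):
        A = rng.normal(0, 1, (2, 3))
        A_hat, L = rescale_sensitivity(A, alpha_spatial=0.01)
        col = np.einsum("ij,ij->j", A, A)
        expected_L = np.sqrt(col + 0.01 * col.max())
        np.testing.assert_allclose(L, expected_L, rtol=1e-12)
        np.testing.assert_allclose(A_hat, A / expected_L, rtol=1e-12)

    def test_columns_bounded_by_one_in_small_alpha_limit(self, rng):
        A = rng.normal(0, 1, (4, 7))
        A_hat, _ = rescale_sensitivity(A, alpha_spatial=1e-12)
        norms = np.linalg.norm(A_hat, axis=0)
        assert np.all(norms <= 1.0 + 1e-9)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-5)

    def test_highest_sensitivity_columns_downweighted_most(self, rng):
        A = rng.normal(0, 1, (5, 6))
        A[:, 0] *= 10  # a "superficial" column
        _, L = rescale_sensitivity(A, 0.001)
        assert L[0] == L.max()

    def test_nonpositive_alpha_error(self):
        with pytest.raises(ValueError, match="positive"):
            rescale_sensitivity(np.eye(2), alpha_spatial=0.0)

    def test_degenerate_matrix_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescale_sensitivity(np.zeros((3, 4)), 0.001)


class TestReconstruct:
    def test_zero_measurement_zero_image(self, rng):
        A = rng.normal(0, 1, (3, 5))
        x = reconstruct(np.zeros(3), A, ReconConfig())
        np.testing.assert_allclose(x, 0.0)

    @pytest.mark.parametrize("shape", [(3, 5), (6, 12), (10, 20)])
    def test_matches_dense_oracle(self, shape, rng):
        A = np.abs(rng.normal(0, 1, shape))
        y = rng.normal(0, 1, shape[0])
        cfg = ReconConfig(alpha_spatial=0.001, alpha_meas=0.001)
        got = reconstruct(y, A, cfg)
        expected = _dense_oracle(y, A, 0.001, 0.001)
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_small_regularization_reproduces_measurements(self, rng):
        A = rng.normal(0, 1, (4, 9))
        x_true = rng.normal(0, 1, 9)
        y = A @ x_true
        cfg = ReconConfig(alpha_spatial=0.001, alpha_meas=1e-12)
        x = reconstruct(y, A, cfg)
        assert np.linalg.norm(A @ x - y) / np.linalg.norm(y) < 1e-6

    def test_dimension_mismatch_error(self, rng):
        A = rng.normal(0, 1, (3, 5))
        with pytest.raises(ValueError, match="length"):
            reconstruct(np.zeros(4), A, ReconConfig())

    def test_nonfinite_measurement_error(self, rng):
        A = rng.normal(0, 1, (3, 5))
        with pytest.raises(ValueError, match="finite"):
            reconstruct(np.array([1.0, np.nan, 0.0]), A, ReconConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(alpha_spatial=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(mode="both")

    def test_brain_only_matches_plain_tikhonov_on_brain_columns(self, rng):
        A = np.abs(rng.normal(0, 1, (4, 8)))
        brain = np.zeros(8, bool)
        brain[:4] = True
        y = rng.normal(0, 1, 4)
        got = reconstruct(y, A, ReconConfig(mode="brain_only"), brain_mask=brain)
        Ab = A[:, :4]
        M = Ab @ Ab.T
        lam = 0.001 * np.diag(M).max()
        expected = Ab.T @ np.linalg.inv(M + lam * np.eye(4)) @ y
        np.testing.assert_allclose(got[:4], expected, rtol=1e-10)
        np.testing.assert_allclose(got[4:], 0.0)


@pytest.fixture(scope="module")
def fine_systems(hd_layout, sparse_layout):
    """Both arrays at the model's default 5 mm sampling: brain/scalp
    separation depends on resolving the superficial sensitivity peak."""
    from hdnirs.forward import HeadModel, build_sensitivity

    head = HeadModel.for_layout(hd_layout, sparse_layout, spacing=5.0)
    return {
        lay.name: stack_multispectral(build_sensitivity(lay, head))
        for lay in (hd_layout, sparse_layout)
    }


class TestBrainScalpSeparation:
    def test_superficial_input_lands_on_scalp(self, fine_systems):
        """>= 80% of image energy on the scalp for scalp-only truth."""
        system = fine_systems["hd"]
        V = system.n_vertices
        scalp = system.sensitivity.scalp_mask
        x0 = np.zeros(2 * V)
        x0[:V][scalp] = 1.0
        x0[V:][scalp] = -0.3
        y = system.A @ x0
        img = ImageReconstructor(system, ReconConfig()).image(y)
        assert img.surface_energy_fraction("scalp") >= 0.80

    def test_hd_separates_cortical_input_better_than_sparse(self, fine_systems):
        """With overlapping multidistance channels the HD array keeps
        cortical input on the brain surface better than the sparse grid."""
        fracs = {}
        amps = {}
        for name, system in fine_systems.items():
            V = system.n_vertices
            verts = system.sensitivity.vertices
            scalp = system.sensitivity.scalp_mask
            d = np.hypot(verts["x"] + 90.0, verts["y"]).to_numpy()
            act = np.flatnonzero(~scalp & (d <= 12.0))
            x0 = np.zeros(2 * V)
            x0[act] = 1.0
            x0[V + act] = -0.25
            img = ImageReconstructor(system, ReconConfig()).image(system.A @ x0)
            fracs[name] = img.surface_energy_fraction("brain")
            amps[name] = img.hbo[act].mean()
        assert fracs["hd"] > fracs["sparse"]
        assert amps["hd"] > amps["sparse"]


class TestImageTimecourse:
    def test_zero_hrf_zero_images(self, system_hd):
        C = system_hd.n_channels
        times = np.arange(-2, 23.1, 0.5)
        hrf = np.zeros((C, 2, len(times)))
        t, images = image_timecourse(hrf, times, system_hd)
        assert all(np.allclose(im.hbo, 0) and np.allclose(im.hbr, 0)
                   for im in images)

    def test_peak_time_preserved(self, system_hd, head):
        """Peak-vertex image time course peaks within 2 s of channel peak."""
        from hdnirs.synth import block_response, make_ground_truth

        truth = make_ground_truth(head, seed=1)
        V = system_hd.n_vertices
        fs = 2.0
        times = np.arange(-2, 23.01, 1 / fs)
        resp = block_response(fs, length=25.0 + 2)[: len(times)]
        resp = np.concatenate([np.zeros(int(2 * fs)), resp])[: len(times)]
        act = truth.active_brain_vertices["incongruent"]
        x0 = np.zeros(2 * V)
        x0[act] = 1.0
        x0[V + act] = -0.25
        y_peak = system_hd.A @ x0  # OD pattern at unit response
        od = np.outer(y_peak, resp)  # (2C, T)
        # convert stacked OD back to per-channel conc via exact MBLL
        from hdnirs.extinction import extinction_matrix

        E = extinction_matrix()
        C = system_hd.n_channels
        sep = system_hd.sensitivity.channels["separation"].to_numpy()
        conc = np.einsum(
            "kw,wct->ckt", np.linalg.inv(E),
            np.stack([od[:C], od[C:]]) / sep[None, :, None],
        )
        t, images = image_timecourse(conc, times, system_hd, step=1.0)
        brain = images[0].brain_mask
        series = np.array([im.hbo[brain] for im in images])
        peak_vertex = series.max(axis=0).argmax()
        t_img_peak = t[series[:, peak_vertex].argmax()]
        t_true_peak = times[resp.argmax()]
        assert abs(t_img_peak - t_true_peak) <= 2.0

    def test_vertex_set_mean_is_elementwise_average(self, system_hd, rng):
        C = system_hd.n_channels
        times = np.arange(0, 5.0, 1.0)
        hrf = rng.normal(0, 0.1, (C, 2, len(times)))
        _, images = image_timecourse(hrf, times, system_hd, step=1.0)
        vids = np.array([0, 5, 9])
        means = [im.hbo[vids].mean() for im in images]
        per_vertex = np.array([[im.hbo[v] for v in vids] for im in images])
        np.testing.assert_allclose(means, per_vertex.mean(axis=1))

    def test_empty_window_error(self, system_hd):
        C = system_hd.n_channels
        times = np.arange(0, 5.0, 1.0)
        with pytest.raises(ValueError, match="window"):
            image_timecourse(np.zeros((C, 2, 5)), times, system_hd,
                             window=(3.0, 1.0))


def test_stack_multispectral_block_structure(S_sparse):
    from hdnirs.extinction import extinction_matrix

    system = stack_multispectral(S_sparse)
    E = extinction_matrix(S_sparse.wavelengths)
    C, V = S_sparse.n_channels, S_sparse.n_vertices
    np.testing.assert_allclose(system.A[:C, :V], E[0, 0] * S_sparse.values[0])
    np.testing.assert_allclose(system.A[C:, V:], E[1, 1] * S_sparse.values[1])


def test_hrf_to_od_inverts_beer_lambert(rng):
    """hrf_to_od is the exact forward of the od_to_conc inverse."""
    import pandas as pd

    from hdnirs.preprocess import od_to_conc
    from hdnirs.synth import Recording

    C, T = 3, 40
    conc = rng.normal(0, 1, (C, 2, T))
    sep = np.array([30.0, 19.0, 33.0])
    od = hrf_to_od(conc, sep)
    od_cube = np.stack([od[:C], od[C:]], axis=1)
    channels = pd.DataFrame(
        {"source_id": range(C), "detector_id": range(C), "separation": sep,
         "distance_class": ["NN30"] * C, "is_short": [False] * C}
    )
    rec = Recording(layout_name="t", fs=1.0, stage="od", data=od_cube,
                    schedule=None, channels=channels)
    back = od_to_conc(rec)
    np.testing.assert_allclose(back.data, conc, rtol=1e-10, atol=1e-12)
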