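"""GED spatial filtering: filters, covariances, eigenproblem, selection."""

import numpy as np
import pytest
from scipy import signal as sps

import spindlesep as sp
from spindlesep.eeg_io import Recording
from spindlesep.ged import (band_covariances, component_spectra,
                            design_fir_bandpass, filter_zero_phase, fit_ged,
                            ged, select_components)
from spindlesep.laplacian import apply_csd, build_csd_transform
from spindlesep.spectral import epoch_matrix
from spindlesep.synth import SynthParams, gaussian_bump_topo, simulate_subject

FS = 400.0


class TestFirDesign:
    def test_dc_null_and_band_response(self):
        k = design_fir_bandpass(9.0, 12.0, FS)  # default order 13200
        assert abs(k.sum()) <= 1e-6
        w, h = sps.freqz(k, worN=[8.5, 9.0, 10.5, 12.0, 12.5], fs=FS)
        mag = np.abs(h)
        assert mag[2] >= 0.99          # mid-band
        assert mag[0] <= 0.01          # lo - 0.5 Hz
        assert mag[4] <= 0.01          # hi + 0.5 Hz

    def test_sinusoid_pass_and_stop(self):
        order = 2000
        k = design_fir_bandpass(9.0, 12.0, FS, order=order)
        t = np.arange(int(60 * FS)) / FS
        mid = np.sin(2 * np.pi * 10.5 * t)
        stop = np.sin(2 * np.pi * 8.0 * t)
        sl = slice(order, -order)  # away from edges
        y_mid = filter_zero_phase(mid, k)[sl]
        y_stop = filter_zero_phase(stop, k)[sl]
        assert np.abs(y_mid).max() == pytest.approx(1.0, abs=0.01)
        atten_db = 20 * np.log10(np.abs(y_stop).max() / 1.0)
        assert atten_db <= -40

    def test_guards(self):
        with pytest.raises(ValueError):
            design_fir_bandpass(12.0, 9.0, FS)
        with pytest.raises(ValueError):
            design_fir_bandpass(9.0, 12.0, FS, order=101)
        with pytest.raises(ValueError, match="length"):
            filter_zero_phase(np.zeros(100), np.zeros(201))


class TestBandCovariances:
    def make_rec(self, data):
        return Recording(data=data, fs=FS,
                         labels=[f"E{i}" for i in range(data.shape[0])],
                         laplacian_applied=True)

    def test_white_noise_covariances_near_diagonal(self, rng):
        data = rng.standard_normal((4, int(120 * FS)))
        rec = self.make_rec(data)
        S, F = band_covariances(rec, data, order=2000)
        for C in (S, F):
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            off = np.abs(C[~np.eye(4, dtype=bool)]).max()
            # off-diagonals shrink like 1/sqrt(T) of the diagonal scale
            assert off < 5.0 * C.diagonal().mean() / np.sqrt(
                data.shape[1] * 3.0 / FS  # ~effective band samples
            )

    def test_rank_one_source_structure(self, rng):
        a = np.array([1.0, 0.5, -0.25, 0.1])
        t = np.arange(int(120 * FS)) / FS
        src = np.sin(2 * np.pi * 10.5 * t)
        data = np.outer(a, src) + 1e-4 * rng.standard_normal((4, len(t)))
        rec = self.make_rec(data)
        S, F = band_covariances(rec, data, order=2000)
        # S ~ sigma^2 a a^T: dominant eigenvector parallel to a
        evals, evecs = np.linalg.eigh(S)
        v = evecs[:, -1]
        cos = abs(v @ a) / np.linalg.norm(a)
        assert cos > 0.999
        assert np.trace(F) < 0.01 * np.trace(S)


def rayleigh_oracle(S, F, n_draws=200_000, seed=0):
    """Dense random search over unit vectors for max/min of w'Sw / w'Fw."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_draws, S.shape[0]))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    q = np.einsum("ij,jk,ik->i", W, S, W) / np.einsum("ij,jk,ik->i", W, F, W)
    return q.max(), q.min()


class TestGed:
    def test_identical_matrices_give_unit_eigenvalues(self, rng):
        A = rng.standard_normal((5, 5))
        S = A @ A.T + np.eye(5)
        model = ged(S, S, shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-10)

    def test_diagonal_case(self):
        model = ged(np.diag([2.0, 1.0]), np.eye(2), shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, [2.0, 1.0])
        np.testing.assert_allclose(np.abs(model.W[:, 0]), [1.0, 0.0],
                                   atol=1e-12)

    def test_rayleigh_quotient_extremality(self, rng):
        for trial in range(3):
            A = rng.standard_normal((6, 6))
            B = rng.standard_normal((6, 6))
            S = A @ A.T + 0.1 * np.eye(6)
            F = B @ B.T + 0.1 * np.eye(6)
            model = ged(S, F, shrinkage=0.0)
            quot = S.diagonal() / F.diagonal()
            assert model.eigenvalues[0] >= quot.max() - 1e-10
            assert model.eigenvalues[-1] <= quot.min() + 1e-10

    def test_matches_dense_search_oracle(self, rng):
        A = rng.standard_normal((3, 3))
        B = rng.standard_normal((3, 3))
        S = A @ A.T + 0.1 * np.eye(3)
        F = B @ B.T + 0.1 * np.eye(3)
        model = ged(S, F, shrinkage=0.0)
        hi, lo = rayleigh_oracle(S, F)
        assert hi <= model.eigenvalues[0] + 1e-9
        assert lo >= model.eigenvalues[-1] - 1e-9
        assert model.eigenvalues[0] == pytest.approx(hi, rel=1e-3)
        assert model.eigenvalues[-1] == pytest.approx(lo, rel=1e-3)

    def test_guards(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            ged(rng.standard_normal((3, 3)), np.eye(3))
        with pytest.raises(ValueError, match="zero"):
            ged(np.eye(3), np.zeros((3, 3)))

    def test_filters_unit_norm_sign_fixed(self, rng):
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        model = ged(A @ A.T + np.eye(5), B @ B.T + np.eye(5))
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0)
        for col in model.W.T:
            assert col[np.argmax(np.abs(col))] > 0


@pytest.fixture(scope="module")
def planted_subject(montage16):
    slow_topo = gaussian_bump_topo(montage16, montage16.xyz[0], 0.9)
    fast_topo = gaussian_bump_topo(montage16, montage16.xyz[5], 0.9)
    params = SynthParams(
        n_channels=16, minutes_n2=3.0, minutes_n3=0.0, seed=17,
        slow_freq=10.6, fast_freq=13.8, slow_topo=slow_topo,
        fast_topo=fast_topo,
    )
    rec, hyp, gt = simulate_subject(params, montage16)
    op = build_csd_transform(montage16)
    lap = apply_csd(rec, op)
    return lap, hyp, gt


class TestComponentPipeline:
    def test_identity_w_reproduces_channel_spectra(self, planted_subject):
        lap, hyp, _ = planted_subject
        ep = epoch_matrix(lap, hyp, "N2")
        model = ged(np.eye(16), np.eye(16))
        model.W = np.eye(16)
        spec = component_spectra(model, ep, lap.fs)
        from spindlesep.spectral import derivative_welch_psd, rescale_01

        chan = rescale_01(derivative_welch_psd(ep, lap.fs))
        np.testing.assert_allclose(spec.power, chan.power, rtol=1e-10)
        assert spec.power.min(axis=1) == pytest.approx(0.0)
        assert spec.power.max(axis=1) == pytest.approx(1.0)

    def test_recovers_planted_frequencies(self, planted_subject):
        lap, hyp, gt = planted_subject
        ep = epoch_matrix(lap, hyp, "N2")
        model = fit_ged(lap, ep, order=4000)
        assert model.selected_slow is not None
        assert model.selected_fast is not None
        assert abs(model.selected_slow.freq - gt.slow_freq) <= 0.2
        assert abs(model.selected_fast.freq - gt.fast_freq) <= 0.2
        # slow favored at the top of the eigenvalue ordering, fast at bottom
        assert model.selected_slow.component < model.selected_fast.component

    def test_manual_policy_forces_component(self, planted_subject):
        lap, hyp, _ = planted_subject
        ep = epoch_matrix(lap, hyp, "N2")
        model = fit_ged(lap, ep, order=4000)
        slow, fast = select_components(
            model, policy="manual",
            manual_slow=model.selected_slow.component,
            manual_fast=model.selected_fast.component,
        )
        assert slow.component == model.selected_slow.component
        assert slow.freq == model.selected_slow.freq
        assert fast.freq == model.selected_fast.freq

    def test_requires_laplacian_input(self, planted_subject, montage16):
        lap, hyp, _ = planted_subject
        raw = Recording(data=lap.data, fs=lap.fs, labels=lap.labels,
                        laplacian_applied=False)
        with pytest.raises(ValueError, match="Laplacian"):
            fit_ged(raw, epoch_matrix(raw, hyp, "N2"), order=4000)
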