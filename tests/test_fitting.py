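"""Fitting-module tests: exact recovery, smoothing arithmetic, degeneracies,
flag accounting and noise-model bias."""

import numpy as np
import pytest

import hdomri as h
from hdomri.core_model import MEGEDataset, MEGEProtocol, SignalParams
from hdomri.fitting import (FLAG_BOUND, FLAG_LOW_SIGNAL, FLAG_OK,
                            _spgr_resid_jac, fit_t2star_monoexp,
                            times_to_rates)
from tests.conftest import small_protocol


class TestFlipAngleMap:
    def test_noiseless_exact_recovery(self, noiseless_fit):
        """Stage 1 on noise-free data recovers per-voxel flip angle, R1 and
        amplitude to 0.1% relative."""
        truth, ds, stage1, _, _ = noiseless_fit
        brain = truth.label_map > 0
        fitted = brain & (stage1.qc_flags == FLAG_OK)
        assert fitted.sum() > 0.9 * brain.sum()
        true_alpha = truth.b1_field * ds.protocol.nominal_flip
        assert np.allclose(stage1.flip_angle[fitted], true_alpha[fitted],
                           rtol=1e-3)
        assert np.allclose(stage1.R1[fitted],
                           1000.0 / truth.T1_map[fitted], rtol=1e-3)

    def test_needs_three_TRs(self):
        proto = small_protocol(matrix=(16, 16, 10), n_TR=2)
        data = np.ones((16, 16, 10, proto.n_echoes, 2))
        with pytest.raises(ValueError):
            h.fit_flip_angle_map(MEGEDataset(data=data, protocol=proto))

    def test_flat_recovery_curve_hits_bound(self, proto_small):
        """A TR-independent signal carries no R1 information: the fit lands
        on a parameter bound and is flagged."""
        shape = proto_small.matrix
        data = np.zeros(shape + (proto_small.n_echoes, proto_small.n_TR))
        data[8, 8, 5] = 1.0  # constant across echoes and TRs
        ds = MEGEDataset(data=data, protocol=proto_small)
        maps = h.fit_flip_angle_map(ds)
        assert maps.qc_flags[8, 8, 5] == FLAG_BOUND

    def test_flag_partition_complete(self, snr16_fit):
        """Every voxel is exactly one of fitted (finite parameters) or
        flagged-skipped (NaN) — no silent omissions."""
        _, _, stage1, _, _ = snr16_fit
        fitted = np.isin(stage1.qc_flags, (FLAG_OK, FLAG_BOUND))
        assert np.all(np.isfinite(stage1.flip_angle[fitted]))
        skipped = stage1.qc_flags == FLAG_LOW_SIGNAL
        assert np.all(np.isnan(stage1.flip_angle[skipped]))
        assert np.all(fitted | skipped | (stage1.qc_flags == 3))


class TestSmoothFlipAngleMap:
    def test_uniform_map_unchanged(self):
        a = np.full((9, 9, 9), 57.0)
        out = h.smooth_flip_angle_map(a)
        assert np.allclose(out, 57.0)

    def test_impulse_spreads_by_one_125th(self):
        """A single valid impulse on a zero (valid) background contributes
        v/125 to each full-neighbourhood voxel."""
        a = np.zeros((11, 11, 11))
        a[5, 5, 5] = 125.0
        out = h.smooth_flip_angle_map(a)
        assert out[5, 5, 5] == pytest.approx(1.0)
        assert out[4, 6, 5] == pytest.approx(1.0)
        assert out[5, 5, 3] == pytest.approx(1.0)

    def test_corner_neighbourhood_shrinks(self):
        """A corner voxel averages over its 27 in-volume neighbours only
        (brute-force neighbourhood count)."""
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8))
        out = h.smooth_flip_angle_map(a)
        assert out[0, 0, 0] == pytest.approx(a[:3, :3, :3].mean())
        assert out[7, 0, 4] == pytest.approx(a[5:, :3, 2:7].mean())

    def test_invalid_voxels_do_not_contribute(self):
        a = np.full((9, 9, 9), 10.0)
        qc = np.zeros((9, 9, 9), int)
        a[4, 4, 4] = 1e6
        qc[4, 4, 4] = FLAG_LOW_SIGNAL
        out = h.smooth_flip_angle_map(a, qc)
        assert np.nanmax(out) == pytest.approx(10.0)

    def test_isolated_invalid_region_stays_nan(self):
        a = np.full((9, 9, 9), np.nan)
        out = h.smooth_flip_angle_map(a)
        assert np.all(np.isnan(out))


class TestRelaxationMaps:
    def test_noiseless_exact_recovery(self, noiseless_fit):
        """Dual fit with the (constant-B1) smoothed flip angle recovers the
        T1/T2* maps to 0.1% relative everywhere fitted."""
        truth, ds, _, _, maps = noiseless_fit
        brain = truth.label_map > 0
        ok = brain & (maps.qc_flags == FLAG_OK)
        assert ok.sum() > 0.9 * brain.sum()
        assert np.allclose(maps.T1_ms[ok], truth.T1_map[ok], rtol=1e-3)
        assert np.allclose(maps.T2star_ms[ok], truth.T2star_map[ok], rtol=1e-3)
        assert np.allclose(maps.amplitude[ok], truth.amplitude_map[ok],
                           rtol=1e-3)

    def test_underdetermined_grid_rejected(self):
        proto = MEGEProtocol(TR_list=(100.0,), averages_per_TR=(1,), TE1=5.0,
                             deltaTE=5.0, n_echoes=1, nominal_flip=90.0,
                             FOV=(48.0, 48.0, 80.0), voxel_size=(6.0, 6.0, 10.0))
        data = np.ones((8, 8, 8, 1, 1))
        ds = MEGEDataset(data=data, protocol=proto)
        with pytest.raises(ValueError):
            h.fit_relaxation_maps(ds, np.full((8, 8, 8), 90.0))

    def test_misaligned_alpha_map_rejected(self, noiseless_phantom):
        _, ds = noiseless_phantom
        with pytest.raises(ValueError):
            h.fit_relaxation_maps(ds, np.full((4, 4, 4), 60.0))

    def test_rician_bias_quantified_at_snr16(self):
        """Magnitude (Rician) noise at SNR 16 inflates least-squares T2*
        relative to the Gaussian-noise fit of the same phantom; the
        inflation stays modest (accepted, not corrected)."""
        proto = small_protocol(matrix=(16, 16, 10))
        medians = {}
        for model in ("gaussian", "rician"):
            truth = h.build_phantom(grid_shape=proto.matrix,
                                    noise_model=model, seed=21)
            truth.noise_sigma = h.sigma_for_snr(truth, proto, 16.0)
            ds = h.synthesize_mege(truth, proto)
            stage1 = h.fit_flip_angle_map(ds)
            alpha = h.smooth_flip_angle_map(stage1.flip_angle,
                                            stage1.qc_flags)
            maps = h.fit_relaxation_maps(ds, alpha, r1_init=stage1.R1)
            gm = (truth.label_map == 2) & (maps.qc_flags == FLAG_OK)
            medians[model] = (np.nanmedian(maps.T1_ms[gm]),
                              np.nanmedian(maps.T2star_ms[gm]))
        t2_ratio = medians["rician"][1] / medians["gaussian"][1]
        assert 1.0 <= t2_ratio < 1.15  # Rician floor flattens the TE decay
        assert 0.8 < medians["rician"][0] / medians["gaussian"][0] < 1.3


class TestMonoExpT2star:
    def _single_tr_dataset(self, S0, T2s, TE1=2.5, dTE=2.57, n=15,
                           shape=(8, 8, 8)):
        proto = MEGEProtocol(TR_list=(41.0,), averages_per_TR=(1,), TE1=TE1,
                             deltaTE=dTE, n_echoes=n, nominal_flip=15.0,
                             FOV=(24.0, 24.0, 40.0), voxel_size=(3.0, 3.0, 5.0))
        TEs = np.asarray(proto.TE_list)
        data = np.zeros(shape + (n, 1))
        data[...] = (S0 * np.exp(-TEs / T2s))[:, None]
        return MEGEDataset(data=data, protocol=proto)

    def test_proton_protocol_recovery(self):
        """Noiseless decay with T2* = 24 ms sampled by the 15-echo proton
        protocol is recovered to 0.01%."""
        ds = self._single_tr_dataset(100.0, 24.0)
        maps = fit_t2star_monoexp(ds)
        assert maps.T2star_ms[4, 4, 4] == pytest.approx(24.0, rel=1e-4)

    def test_two_point_exact_solution(self):
        """Two samples determine T2* exactly: S2/S1 = exp(-dTE/T2*)."""
        ds = self._single_tr_dataset(100.0, 24.0, TE1=24.0, dTE=24.0, n=2)
        maps = fit_t2star_monoexp(ds)
        assert maps.T2star_ms[0, 0, 0] == pytest.approx(24.0, rel=1e-6)

    def test_constant_signal_flagged_at_bound(self):
        ds = self._single_tr_dataset(100.0, 24.0)
        ds.data[...] = 50.0
        maps = fit_t2star_monoexp(ds)
        assert maps.qc_flags[4, 4, 4] == FLAG_BOUND
        assert maps.R2star[4, 4, 4] == pytest.approx(1.0, rel=1e-3)

    def test_needs_two_echoes(self):
        proto = MEGEProtocol(TR_list=(41.0,), averages_per_TR=(1,), TE1=2.5,
                             deltaTE=2.5, n_echoes=1, nominal_flip=15.0,
                             FOV=(24.0, 24.0, 40.0), voxel_size=(3.0, 3.0, 5.0))
        ds = MEGEDataset(data=np.ones((8, 8, 8, 1, 1)), protocol=proto)
        with pytest.raises(ValueError):
            fit_t2star_monoexp(ds)


class TestRatesToTimes:
    def test_known_values_and_round_trip(self):
        maps = h.QuantMaps(R1=np.array([[[1.9608]]]),
                           R2star=np.array([[[33.333]]]))
        times = h.rates_to_times(maps)
        assert times["T1_ms"][0, 0, 0] == pytest.approx(510.0, abs=0.05)
        assert times["T2star_ms"][0, 0, 0] == pytest.approx(30.0, abs=1e-3)
        back = times_to_rates(times["T1_ms"])
        assert back[0, 0, 0] == pytest.approx(1.9608)

    def test_nan_propagates(self):
        maps = h.QuantMaps(R1=np.array([np.nan, 2.0]))
        out = h.rates_to_times(maps)
        assert np.isnan(out["T1_ms"][0]) and out["T1_ms"][1] == 500.0

    def test_empty_maps_rejected(self):
        with pytest.raises(ValueError):
            h.rates_to_times(h.QuantMaps())
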