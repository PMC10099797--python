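"""Shared fixtures: protocols and phantom datasets reused across the suite.

The fitted-map fixtures are session-scoped because voxel-wise fitting is
the expensive step; every test reads them, none mutates them.
"""

import numpy as np
import pytest

import hdomri as h


def small_protocol(matrix=(16, 16, 10), n_TR=5, n_echoes=6):
    """Steady-state 2H relaxometry protocol shrunk to a small matrix."""
    return h.MEGEProtocol(
        TR_list=(68.0, 136.0, 272.0, 544.0, 816.0)[:n_TR],
        averages_per_TR=(8, 4, 2, 1, 1)[:n_TR],
        TE1=4.3, deltaTE=8.4, n_echoes=n_echoes, nominal_flip=60.0,
        FOV=tuple(m * v for m, v in zip(matrix, (6.0, 6.0, 10.0))),
        voxel_size=(6.0, 6.0, 10.0))


@pytest.fixture(scope="session")
def proto_small():
    return small_protocol()


@pytest.fixture(scope="session")
def noiseless_phantom(proto_small):
    """Noiseless phantom with constant B1 (smoothing-neutral) and zero
    tissue SDs, for exact-recovery checks."""
    tissue = {k: h.phantom.TissueParams(v.T1_mean, 0.0, v.T2star_mean, 0.0,
                                        v.amplitude)
              for k, v in h.phantom.TISSUE_DEFAULTS.items()}
    truth = h.build_phantom(grid_shape=proto_small.matrix,
                            tissue_params=tissue,
                            b1_spec={"kind": "constant", "value": 0.95},
                            noise_sigma=0.0, noise_model="gaussian", seed=11)
    return truth, h.synthesize_mege(truth, proto_small)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_phantom):
    truth, ds = noiseless_phantom
    stage1 = h.fit_flip_angle_map(ds)
    alpha = h.smooth_flip_angle_map(stage1.flip_angle, stage1.qc_flags)
    maps = h.fit_relaxation_maps(ds, alpha, r1_init=stage1.R1)
    return truth, ds, stage1, alpha, maps


@pytest.fixture(scope="session")
def snr16_protocol():
    return small_protocol(matrix=(28, 28, 14))


@pytest.fixture(scope="session")
def snr16_phantom(snr16_protocol):
    """Default phantom (tissue SDs, smooth B1) with Gaussian noise at the
    study's echo-summed SNR of 16."""
    truth = h.build_phantom(grid_shape=snr16_protocol.matrix,
                            noise_model="gaussian", seed=5)
    truth.noise_sigma = h.sigma_for_snr(truth, snr16_protocol, 16.0)
    return truth, h.synthesize_mege(truth, snr16_protocol)


@pytest.fixture(scope="session")
def snr16_fit(snr16_phantom):
    truth, ds = snr16_phantom
    stage1 = h.fit_flip_angle_map(ds)
    alpha = h.smooth_flip_angle_map(stage1.flip_angle, stage1.qc_flags)
    maps = h.fit_relaxation_maps(ds, alpha, r1_init=stage1.R1)
    return truth, ds, stage1, alpha, maps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
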