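"""Voxel-wise estimation of flip-angle, R1, R2* and amplitude maps.

The two-stage procedure for multi-TR/multi-echo gradient-echo magnitude
data:

1. **Flip-angle stage** — the images are summed across echoes at each TR
   and each voxel's TR series is fitted to a saturation-recovery curve
   ``A' sin(a) (1 - E1) / (1 - cos(a) E1)`` for amplitude, flip angle ``a``
   and R1.  The flip-angle map is then smoothed over a 5x5x5 neighbourhood
   (B1 varies smoothly in space; the smoothing suppresses the strong
   single-voxel a-R1 correlation).
2. **Relaxation stage** — with the smoothed flip angle held fixed, the full
   (TR, TE) signal grid is fitted per voxel for amplitude, R1 and R2* by
   minimising the unweighted sum of squared residuals of the spoiled
   gradient-echo model.

Fits use bounded trust-region least squares with analytic Jacobians.
Least squares on magnitude data assumes Gaussian errors; the Rician bias
this leaves at SNR >~ 5 is quantified in the test suite, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .core_model import MEGEDataset

__all__ = [
    "QuantMaps",
    "FLAG_OK",
    "FLAG_LOW_SIGNAL",
    "FLAG_BOUND",
    "FLAG_NONCONV",
    "fit_flip_angle_map",
    "smooth_flip_angle_map",
    "fit_relaxation_maps",
    "fit_t2star_monoexp",
    "rates_to_times",
    "times_to_rates",
]

FLAG_OK = 0
FLAG_LOW_SIGNAL = 1
FLAG_BOUND = 2
FLAG_NONCONV = 3

# Parameter bounds shared by all fits
R1_BOUNDS = (0.2, 20.0)        # 1/s  (T1 between 50 ms and 5 s)
R2STAR_BOUNDS = (1.0, 500.0)   # 1/s  (T2* between 2 ms and 1 s)
ALPHA_BOUNDS_DEG = (1.0, 120.0)

DEFAULT_SIGNAL_THRESHOLD = 0.05  # fraction of the 99th-percentile summed signal


@dataclass
class QuantMaps:
    """Fitted parameter maps with per-voxel quality flags.

    Unfitted voxels carry NaN in the parameter maps and a non-zero flag:
    1 = below the signal threshold (skipped), 2 = converged on a parameter
    bound, 3 = optimiser failed to converge.
    """

    flip_angle: np.ndarray = None
    R1: np.ndarray = None
    R2star: np.ndarray = None
    amplitude: np.ndarray = None
    residual_rms: np.ndarray = None
    qc_flags: np.ndarray = None

    @property
    def T1_ms(self) -> np.ndarray:
        """T1 in ms (NaN where R1 is missing/invalid)."""
        return _rate_to_time_map(self.R1)

    @property
    def T2star_ms(self) -> np.ndarray:
        return _rate_to_time_map(self.R2star)

    def flag_counts(self) -> dict:
        flags, counts = np.unique(self.qc_flags, return_counts=True)
        return {int(f): int(c) for f, c in zip(flags, counts)}


def _rate_to_time_map(rate):
    if rate is None:
        return None
    rate = np.asarray(rate, dtype=float)
    out = np.full(rate.shape, np.nan)
    ok = np.isfinite(rate) & (rate > 0)
    out[ok] = 1000.0 / rate[ok]
    return out


def rates_to_times(maps: QuantMaps) -> dict:
    """Relaxation-time maps in ms: ``T = 1000 / R`` for rates in 1/s.

    Returns ``{"T1_ms": ..., "T2star_ms": ...}`` (entries present for the
    rate maps the input carries); flagged/NaN voxels propagate as NaN.
    The inverse, :func:`times_to_rates`, round-trips exactly.
    """
    out = {}
    if maps.R1 is not None:
        out["T1_ms"] = _rate_to_time_map(maps.R1)
    if maps.R2star is not None:
        out["T2star_ms"] = _rate_to_time_map(maps.R2star)
    if not out:
        raise ValueError("no rate maps to convert")
    return out


def times_to_rates(time_ms):
    """Inverse of :func:`rates_to_times` for a single map (ms -> 1/s)."""
    return _rate_to_time_map(time_ms)  # same reciprocal formula


def _satrec_resid_jac(theta, TR_s, y):
    """Residuals and Jacobian for the saturation-recovery fit.

    theta = (A', alpha_rad, R1_per_s); times in seconds.
    """
    A, alpha, R1 = theta
    E = np.exp(-R1 * TR_s)
    c, s = np.cos(alpha), np.sin(alpha)
    denom = 1.0 - c * E
    f = (1.0 - E) / denom
    model = A * s * f
    dmodel_dA = s * f
    # df/dalpha through c: df/dc = E(1-E)/denom^2, dc/dalpha = -s
    dmodel_dalpha = A * (c * f - s * s * E * (1.0 - E) / denom ** 2)
    # dE/dR1 = -TR*E ; df/dE = (c-1)/denom^2
    dmodel_dR1 = A * s * (1.0 - c) * TR_s * E / denom ** 2
    J = np.stack([dmodel_dA, dmodel_dalpha, dmodel_dR1], axis=-1)
    return model - y, J


def _spgr_resid_jac(theta, alpha, TR_s, TE_s, y):
    """Residuals and Jacobian for the fixed-alpha dual fit.

    theta = (A, R1_per_s, R2star_per_s); TR_s/TE_s are flattened grids.
    """
    A, R1, R2s = theta
    E = np.exp(-R1 * TR_s)
    c, s = np.cos(alpha), np.sin(alpha)
    denom = 1.0 - c * E
    f = (1.0 - E) / denom
    g = np.exp(-R2s * TE_s)
    model = A * s * f * g
    dA = s * f * g
    dR1 = A * s * g * (1.0 - c) * TR_s * E / denom ** 2
    dR2 = -TE_s * model
    return model - y, np.stack([dA, dR1, dR2], axis=-1)


def _classify(res, lower, upper, rtol=1e-4):
    """QC flag for an optimiser result given its box bounds.

    A parameter pinned at a bound takes precedence over a non-convergence
    report: degenerate voxels (e.g. a flat recovery curve) typically crawl
    along a ridge until a bound and exhaust the iteration budget there.
    """
    for x, lo, hi in zip(res.x, lower, upper):
        scale = (hi - lo) if np.isfinite(hi - lo) else max(abs(x), 1.0)
        if (x - lo) < rtol * scale:
            return FLAG_BOUND
        if np.isfinite(hi) and (hi - x) < rtol * scale:
            return FLAG_BOUND
    return FLAG_OK if res.success else FLAG_NONCONV


def _signal_mask(data: MEGEDataset, signal_threshold: float):
    """Foreground mask: threshold on the echo/TR-summed image.

    The threshold is ``signal_threshold`` of the robust maximum (99th
    percentile) measured above the volume median, which estimates the
    magnitude-noise floor of the summed image (on noiseless data the median
    background is zero and this reduces to a plain fractional threshold).
    """
    summed = data.data.sum(axis=(3, 4))
    floor = np.median(summed)
    ref = np.percentile(summed, 99)
    if ref <= floor:  # foreground-dominated volume: plain fractional rule
        return summed > signal_threshold * ref
    return summed > floor + signal_threshold * (ref - floor)


def _empty_maps(shape) -> QuantMaps:
    nan = lambda: np.full(shape, np.nan)
    return QuantMaps(flip_angle=nan(), R1=nan(), R2star=nan(),
                     amplitude=nan(), residual_rms=nan(),
                     qc_flags=np.full(shape, FLAG_LOW_SIGNAL, dtype=np.int8))


def fit_flip_angle_map(data: MEGEDataset,
                       signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
                       n_starts: int = 3) -> QuantMaps:
    """Stage 1: fit the echo-summed TR series per voxel for (A', alpha, R1).

    Voxels whose echo/TR-summed signal falls below ``signal_threshold``
    times the volume's 99th percentile are skipped (flag 1).  The fit is
    multi-started over flip-angle/R1 initial values because the
    three-parameter saturation-recovery problem is ill-conditioned.
    """
    protocol = data.protocol
    if protocol.n_TR < 3:
        raise ValueError("flip-angle fitting needs at least 3 TR values "
                         "(three unknowns)")
    TR_s = np.asarray(protocol.TR_list) / 1000.0
    ysum = data.data.sum(axis=3)  # (x, y, z, nTR)
    mask = _signal_mask(data, signal_threshold)

    maps = _empty_maps(data.grid_shape)
    nominal = np.deg2rad(protocol.nominal_flip)
    lo = np.array([0.0, np.deg2rad(ALPHA_BOUNDS_DEG[0]), R1_BOUNDS[0]])
    hi = np.array([np.inf, np.deg2rad(ALPHA_BOUNDS_DEG[1]), R1_BOUNDS[1]])
    alpha_starts = np.clip(np.array([0.6, 1.0, 1.0, 1.3]) * nominal,
                           lo[1] * 1.1, hi[1] * 0.9)
    r1_starts = np.array([3.0, 2.0, 6.0, 3.0])

    for idx in np.ndindex(*data.grid_shape):
        if not mask[idx]:
            continue
        y = ysum[idx]
        best = None
        for a0, r0 in zip(alpha_starts[:max(n_starts, 1)],
                          r1_starts[:max(n_starts, 1)]):
            x0 = np.array([max(y.max(), 1e-12) * 1.2, a0, r0])
            res = least_squares(
                lambda th: _satrec_resid_jac(th, TR_s, y)[0], x0,
                jac=lambda th: _satrec_resid_jac(th, TR_s, y)[1],
                bounds=(lo, hi), method="trf")
            if best is None or res.cost < best.cost:
                best = res
        maps.amplitude[idx] = best.x[0]
        maps.flip_angle[idx] = np.degrees(best.x[1])
        maps.R1[idx] = best.x[2]
        maps.residual_rms[idx] = np.sqrt(2.0 * best.cost / len(y))
        maps.qc_flags[idx] = _classify(best, lo, hi)
    return maps


def smooth_flip_angle_map(alpha_map, qc_flags=None, size: int = 5,
                          valid_flags=(FLAG_OK, FLAG_BOUND)):
    """Smooth the flip-angle map by averaging valid voxels in a
    ``size``^3 neighbourhood.

    A voxel's smoothed value is the mean over the in-volume voxels of its
    neighbourhood whose flag is in ``valid_flags`` (the boundary
    neighbourhood simply shrinks).  Voxels with no valid neighbour at all
    stay NaN.

    Bound-hit voxels (flag 2) are included by default: at realistic noise a
    large fraction of single-voxel saturation-recovery fits pin R1 or alpha
    at a bound, and because the errors of the three parameters are strongly
    correlated, averaging only the unflagged subset selects a biased
    flip-angle population.  Pass ``valid_flags=(0,)`` for strict smoothing.
    """
    alpha_map = np.asarray(alpha_map, dtype=float)
    if alpha_map.ndim != 3:
        raise ValueError("flip-angle map must be 3-D")
    if qc_flags is None:
        valid = np.isfinite(alpha_map)
    else:
        valid = np.isin(qc_flags, valid_flags) & np.isfinite(alpha_map)
    n = size ** 3
    sums = ndimage.uniform_filter(np.where(valid, alpha_map, 0.0),
                                  size=size, mode="constant") * n
    counts = ndimage.uniform_filter(valid.astype(float),
                                    size=size, mode="constant") * n
    counts = np.round(counts)
    out = np.full(alpha_map.shape, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def fit_relaxation_maps(data: MEGEDataset, alpha_map,
                        signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
                        r1_init=None) -> QuantMaps:
    """Stage 2: dual fit of the (TR, TE) grid for (A, R1, R2*), alpha fixed.

    Minimises the unweighted sum of squared differences between the spoiled
    gradient-echo model and the measured magnitudes over all TR/TE samples.
    Initialisation: R2* from a log-linear fit of the TE decay at the longest
    TR, R1 from ``r1_init`` (e.g. the stage-1 map) where given, amplitude by
    back-projection of the observed signal onto the unit-amplitude model.

    An ``alpha_map`` of the wrong shape is an error; isolated above-threshold
    voxels whose flip angle is NaN (no valid smoothing neighbour) are skipped
    and keep the low-signal flag.
    """
    protocol = data.protocol
    if protocol.n_TR * protocol.n_echoes < 4:
        raise ValueError("dual fitting needs at least 4 (TR, TE) samples "
                         "for 3 unknowns")
    alpha_map = np.asarray(alpha_map, dtype=float)
    if alpha_map.shape != data.grid_shape:
        raise ValueError("alpha map is not aligned with the data grid")
    TRg, TEg = protocol.timing_grids()
    TR_s = (TRg / 1000.0).T.ravel()  # (nTE*nTR,) matching data order
    TE_s = (TEg / 1000.0).T.ravel()
    TE_last = np.asarray(protocol.TE_list) / 1000.0
    mask = _signal_mask(data, signal_threshold)

    maps = _empty_maps(data.grid_shape)
    lo = np.array([0.0, R1_BOUNDS[0], R2STAR_BOUNDS[0]])
    hi = np.array([np.inf, R1_BOUNDS[1], R2STAR_BOUNDS[1]])

    for idx in np.ndindex(*data.grid_shape):
        if not mask[idx]:
            continue
        alpha_deg = alpha_map[idx]
        if not np.isfinite(alpha_deg):
            # above-threshold voxel with no usable flip angle (e.g. isolated
            # noise spike outside the fitted region): skip, keep flag 1
            continue
        alpha = np.deg2rad(alpha_deg)
        y = data.data[idx].ravel()  # (nTE*nTR,)

        # log-linear R2* start from the TE decay at the longest TR
        ylast = np.maximum(data.data[idx][:, -1], 1e-12)
        slope = np.polyfit(TE_last, np.log(ylast), 1)[0]
        r2s0 = float(np.clip(-slope, R2STAR_BOUNDS[0] * 1.5,
                             R2STAR_BOUNDS[1] * 0.7))
        r10 = 3.0
        if r1_init is not None and np.isfinite(np.asarray(r1_init)[idx]):
            r10 = float(np.clip(np.asarray(r1_init)[idx],
                                R1_BOUNDS[0] * 1.5, R1_BOUNDS[1] * 0.7))
        unit, _ = _spgr_resid_jac((1.0, r10, r2s0), alpha, TR_s, TE_s, 0.0)
        a0 = float(max(np.dot(unit, y) / max(np.dot(unit, unit), 1e-30), 1e-12))

        res = least_squares(
            lambda th: _spgr_resid_jac(th, alpha, TR_s, TE_s, y)[0],
            np.array([a0, r10, r2s0]),
            jac=lambda th: _spgr_resid_jac(th, alpha, TR_s, TE_s, y)[1],
            bounds=(lo, hi), method="trf")
        maps.amplitude[idx] = res.x[0]
        maps.R1[idx] = res.x[1]
        maps.R2star[idx] = res.x[2]
        maps.flip_angle[idx] = alpha_deg
        maps.residual_rms[idx] = np.sqrt(2.0 * res.cost / len(y))
        maps.qc_flags[idx] = _classify(res, lo, hi)
    return maps


def fit_t2star_monoexp(data: MEGEDataset,
                       signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
                       tr_index: int = -1) -> QuantMaps:
    """Mono-exponential TE-decay fit: S(TE) = S0 exp(-R2* TE), per voxel.

    Used for proton R2* mapping from single-TR multi-echo data; for
    multi-TR data the decay at ``tr_index`` is fitted.
    """
    protocol = data.protocol
    if protocol.n_echoes < 2:
        raise ValueError("mono-exponential fitting needs at least 2 echoes")
    TE_s = np.asarray(protocol.TE_list) / 1000.0
    vols = data.data[..., tr_index]  # (x, y, z, nTE)
    mask = _signal_mask(data, signal_threshold)

    maps = _empty_maps(data.grid_shape)
    lo = np.array([0.0, R2STAR_BOUNDS[0]])
    hi = np.array([np.inf, R2STAR_BOUNDS[1]])

    def resid_jac(th, y):
        S0, R2s = th
        g = np.exp(-R2s * TE_s)
        return S0 * g - y, np.stack([g, -TE_s * S0 * g], axis=-1)

    for idx in np.ndindex(*data.grid_shape):
        if not mask[idx]:
            continue
        y = vols[idx]
        coef = np.polyfit(TE_s, np.log(np.maximum(y, 1e-12)), 1)
        r2s0 = float(np.clip(-coef[0], R2STAR_BOUNDS[0] * 1.5,
                             R2STAR_BOUNDS[1] * 0.7))
        s00 = float(max(np.exp(coef[1]), 1e-12))
        res = least_squares(lambda th: resid_jac(th, y)[0],
                            np.array([s00, r2s0]),
                            jac=lambda th: resid_jac(th, y)[1],
                            bounds=(lo, hi), method="trf")
        maps.amplitude[idx] = res.x[0]
        maps.R2star[idx] = res.x[1]
        maps.residual_rms[idx] = np.sqrt(2.0 * res.cost / len(y))
        maps.qc_flags[idx] = _classify(res, lo, hi)
    return maps
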