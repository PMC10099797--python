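"""Closed-form signal models for spoiled multi-echo gradient-echo (MEGE) imaging.

The steady-state spoiled gradient-echo signal at repetition time ``TR``,
echo time ``TE`` and flip angle ``alpha`` is

    S(TR, TE) = A * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1) * exp(-R2star * TE)

with ``E1 = exp(-R1 * TR)``.  ``A`` absorbs proton (here deuteron) density,
coil sensitivity and receiver gain; ``R1 = 1/T1`` and ``R2star = 1/T2*`` are
the longitudinal and effective transverse relaxation rate constants.

Unit conventions used throughout the package:

* times (TR, TE, T1, T2*) are in **milliseconds**;
* rate constants (R1, R2*) are in **1/s**;
* flip angles are in **degrees** at every public interface (converted to
  radians internally).

All model functions broadcast over their timing arguments, so a single code
path serves scalar evaluation, protocol grids and voxel-wise maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalParams",
    "MEGEProtocol",
    "MEGEDataset",
    "spgr_signal",
    "satrec_signal",
    "ernst_angle",
    "rate_to_time",
    "time_to_rate",
]

MS_PER_S = 1000.0


def time_to_rate(time_ms):
    """Convert a relaxation time in ms to a rate constant in 1/s (R = 1000/T)."""
    t = np.asarray(time_ms, dtype=float)
    if np.any(t <= 0):
        raise ValueError("relaxation times must be positive")
    return MS_PER_S / t


def rate_to_time(rate_per_s):
    """Convert a rate constant in 1/s to a relaxation time in ms (T = 1000/R)."""
    r = np.asarray(rate_per_s, dtype=float)
    if np.any(r <= 0):
        raise ValueError("relaxation rates must be positive")
    return MS_PER_S / r


@dataclass(frozen=True)
class SignalParams:
    """Voxel signal parameters: amplitude, flip angle (deg), R1 and R2* (1/s)."""

    amplitude: float
    flip_angle: float
    R1: float
    R2star: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.flip_angle <= 180.0:
            raise ValueError("flip angle must lie in [0, 180] degrees")
        if self.R1 <= 0 or self.R2star <= 0:
            raise ValueError("relaxation rates must be positive")

    @classmethod
    def from_times(cls, amplitude, flip_angle, T1_ms, T2star_ms):
        """Build from relaxation times in ms instead of rates."""
        return cls(amplitude, flip_angle, float(time_to_rate(T1_ms)),
                   float(time_to_rate(T2star_ms)))

    @property
    def T1_ms(self) -> float:
        return float(rate_to_time(self.R1))

    @property
    def T2star_ms(self) -> float:
        return float(rate_to_time(self.R2star))


@dataclass(frozen=True)
class MEGEProtocol:
    """Acquisition protocol for a multi-TR, multi-echo gradient-echo scan.

    Parameters
    ----------
    TR_list
        Repetition times in ms, strictly increasing.
    averages_per_TR
        Number of signal averages acquired at each TR (same length as
        ``TR_list``).  Noise SD on the stored, averaged image scales as
        ``1/sqrt(averages)``.
    TE1, deltaTE
        First echo time and echo spacing in ms; echo ``j`` (1-based) is
        acquired at ``TE1 + (j - 1) * deltaTE``.
    n_echoes
        Number of echoes per excitation.
    nominal_flip
        Prescribed excitation flip angle in degrees; the realised angle is
        ``b1 * nominal_flip`` for a multiplicative B1 field ``b1``.
    FOV, voxel_size
        Field of view and voxel dimensions in mm; the matrix size is
        ``FOV / voxel_size`` and must divide exactly.
    """

    TR_list: tuple
    averages_per_TR: tuple
    TE1: float
    deltaTE: float
    n_echoes: int
    nominal_flip: float
    FOV: tuple = (288.0, 288.0, 240.0)
    voxel_size: tuple = (6.0, 6.0, 10.0)

    def __post_init__(self):
        object.__setattr__(self, "TR_list", tuple(float(t) for t in self.TR_list))
        object.__setattr__(self, "averages_per_TR",
                           tuple(int(a) for a in self.averages_per_TR))
        object.__setattr__(self, "FOV", tuple(float(v) for v in self.FOV))
        object.__setattr__(self, "voxel_size",
                           tuple(float(v) for v in self.voxel_size))
        if len(self.TR_list) == 0:
            raise ValueError("TR_list must be non-empty")
        if any(t <= 0 for t in self.TR_list):
            raise ValueError("all TR values must be positive")
        if any(b <= a for a, b in zip(self.TR_list, self.TR_list[1:])):
            raise ValueError("TR_list must be strictly increasing")
        if len(self.averages_per_TR) != len(self.TR_list):
            raise ValueError("averages_per_TR must match TR_list in length")
        if any(a < 0 for a in self.averages_per_TR):
            raise ValueError("averages must be non-negative")
        if self.TE1 <= 0 or self.deltaTE <= 0:
            raise ValueError("TE1 and deltaTE must be positive")
        if self.n_echoes < 1:
            raise ValueError("need at least one echo")
        if not 0 < self.nominal_flip <= 180:
            raise ValueError("nominal flip angle must lie in (0, 180] degrees")
        if len(self.FOV) != 3 or len(self.voxel_size) != 3:
            raise ValueError("FOV and voxel_size must be length-3")
        for f, v in zip(self.FOV, self.voxel_size):
            if f <= 0 or v <= 0:
                raise ValueError("FOV and voxel dimensions must be positive")
            n = f / v
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"FOV {f} mm is not an integer multiple of voxel {v} mm")

    @property
    def n_TR(self) -> int:
        return len(self.TR_list)

    @property
    def TE_list(self) -> tuple:
        return tuple(self.TE1 + j * self.deltaTE for j in range(self.n_echoes))

    @property
    def matrix(self) -> tuple:
        return tuple(int(round(f / v)) for f, v in zip(self.FOV, self.voxel_size))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def timing_grids(self):
        """Return (TR, TE) grids of shape (n_TR, n_echoes), in ms."""
        return np.meshgrid(np.asarray(self.TR_list),
                           np.asarray(self.TE_list), indexing="ij")


def _check_signal_args(TR, TE, R1, R2star):
    if np.any(np.asarray(TR, dtype=float) <= 0):
        raise ValueError("TR must be positive")
    if np.any(np.asarray(TE, dtype=float) < 0):
        raise ValueError("TE must be non-negative")
    if np.any(np.asarray(R1, dtype=float) <= 0) or np.any(
            np.asarray(R2star, dtype=float) <= 0):
        raise ValueError("relaxation rates must be positive")


def spgr_signal(params: SignalParams, TR, TE):
    """Spoiled gradient-echo signal at the given TR/TE (ms).

    Broadcasts over array-valued ``TR`` and ``TE``; e.g. passing the grids
    from :meth:`MEGEProtocol.timing_grids` evaluates the full protocol.
    """
    _check_signal_args(TR, TE, params.R1, params.R2star)
    TR = np.asarray(TR, dtype=float)
    TE = np.asarray(TE, dtype=float)
    alpha = np.deg2rad(params.flip_angle)
    E1 = np.exp(-params.R1 * TR / MS_PER_S)
    sat = (1.0 - E1) / (1.0 - np.cos(alpha) * E1)
    out = params.amplitude * np.sin(alpha) * sat * np.exp(
        -params.R2star * TE / MS_PER_S)
    return out if out.shape else float(out)


def satrec_signal(amplitude, flip_angle, R1, TR):
    """Saturation-recovery signal: the TE-independent factor of the SPGR model.

    ``A' * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1)`` with
    ``E1 = exp(-R1 * TR)``.  This is the curve fitted to echo-summed data as
    a function of TR; ``A'`` absorbs the (TR-independent) summed TE decay.
    """
    if np.any(np.asarray(amplitude, dtype=float) < 0):
        raise ValueError("amplitude must be >= 0")
    _check_signal_args(TR, 0.0, R1, 1.0)
    TR = np.asarray(TR, dtype=float)
    alpha = np.deg2rad(flip_angle)
    E1 = np.exp(-np.asarray(R1, dtype=float) * TR / MS_PER_S)
    out = amplitude * np.sin(alpha) * (1.0 - E1) / (1.0 - np.cos(alpha) * E1)
    return out if np.ndim(out) else float(out)


def ernst_angle(R1, TR):
    """Flip angle (degrees) maximising the SPGR signal at fixed TR: arccos(E1)."""
    _check_signal_args(TR, 0.0, R1, 1.0)
    E1 = np.exp(-np.asarray(R1, dtype=float) * np.asarray(TR, dtype=float) / MS_PER_S)
    out = np.degrees(np.arccos(E1))
    return out if np.ndim(out) else float(out)


@dataclass
class MEGEDataset:
    """A magnitude MEGE acquisition: 5-D array indexed (x, y, z, echo, TR-index)
    bound to its protocol and a voxel-to-world affine (mm)."""

    data: np.ndarray
    protocol: MEGEProtocol
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("MEGE data must be 5-D (x, y, z, echo, TR)")
        nx, ny, nz, nte, ntr = self.data.shape
        if nte != self.protocol.n_echoes:
            raise ValueError(
                f"echo axis {nte} does not match protocol ({self.protocol.n_echoes})")
        if ntr != self.protocol.n_TR:
            raise ValueError(
                f"TR axis {ntr} does not match protocol ({self.protocol.n_TR})")
        if self.affine is None:
            aff = np.diag(list(self.protocol.voxel_size) + [1.0])
            self.affine = aff
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]


# Reference protocols used across the package ---------------------------------

def steady_state_protocol(n_TR: int = 5, FOV=(288.0, 288.0, 240.0),
                          voxel_size=(6.0, 6.0, 10.0)) -> MEGEProtocol:
    """The sagittal 2H relaxometry protocol: TE1 4.3 ms, dTE 8.4 ms, 6 echoes,
    alpha 60 deg, TR 68/136/272/544/816 ms with 8/4/2/1/1 averages.

    ``n_TR=4`` drops the longest TR (the 4-TR variant used on two of the
    participants, which also used 5 echoes).
    """
    TRs = (68.0, 136.0, 272.0, 544.0, 816.0)[:n_TR]
    avgs = (8, 4, 2, 1, 1)[:n_TR]
    n_echoes = 6 if n_TR == 5 else 5
    return MEGEProtocol(TR_list=TRs, averages_per_TR=avgs, TE1=4.3,
                        deltaTE=8.4, n_echoes=n_echoes, nominal_flip=60.0,
                        FOV=FOV, voxel_size=voxel_size)


def loading_protocol(FOV=(288.0, 288.0, 80.0),
                     voxel_size=(6.0, 6.0, 10.0)) -> MEGEProtocol:
    """The single-TR axial protocol used during the 8-h loading time-course:
    TR 62 ms, 20 averages, alpha 33 deg, 5 echoes, TE1 8.9 ms, dTE 8.4 ms."""
    return MEGEProtocol(TR_list=(62.0,), averages_per_TR=(20,), TE1=8.9,
                        deltaTE=8.4, n_echoes=5, nominal_flip=33.0,
                        FOV=FOV, voxel_size=voxel_size)
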