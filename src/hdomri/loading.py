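"""HDO enrichment quantification for oral D2O loading.

Ingested D2O dilutes into total body water (TBW).  Because each D2O
molecule carries two deuterons on two hydrogen sites, the added deuterium
atom fraction equals the ratio of imbibed D2O volume to TBW volume; the
natural-abundance baseline is 0.015 atom %.  Spectroscopy-based estimates
scale an integrated HDO signal by the signal measured at natural abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NATURAL_ABUNDANCE_PCT = 0.015


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose: time (minutes since first dose), solution volume (ml)
    and D2O volume fraction of the solution."""

    time: float
    volume: float
    d2o_fraction: float = 0.70

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.volume <= 0:
            raise ValueError("dose volume must be positive")
        if not 0 < self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must lie in (0, 1]")

    @property
    def d2o_volume(self) -> float:
        """Millilitres of pure D2O delivered by this dose."""
        return self.volume * self.d2o_fraction


@dataclass
class EnrichmentSeries:
    """Deuterium enrichment (atom %) sampled at given times (minutes)."""

    times: np.ndarray
    enrichment: np.ndarray
    provenance: str = "synthetic"  # {from_dose, from_spectra, synthetic}

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        if self.times.shape != self.enrichment.shape:
            raise ValueError("times and enrichment must have the same shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")
        if np.any(self.enrichment < 0):
            raise ValueError("enrichment must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times,
                             "enrichment_pct": self.enrichment})


# Watson anthropometric TBW equations (litres); the standard regression
# estimates used when isotope-dilution TBW is unavailable.
def total_body_water(sex: str, age: float, height: float, mass: float,
                     method: str = "watson", fraction: float = 0.60) -> float:
    """Total body water in litres.

    ``method="watson"`` uses the published sex-specific regressions on age
    (years), height (cm) and mass (kg); ``method="fraction"`` returns
    ``fraction * mass`` litres (1 kg of body water ~ 1 L).
    """
    if age <= 0 or height <= 0 or mass <= 0:
        raise ValueError("anthropometrics must be positive")
    if method == "watson":
        s = sex.lower()
        if s in ("m", "male"):
            return 2.447 - 0.09156 * age + 0.1074 * height + 0.3362 * mass
        if s in ("f", "female"):
            return -2.097 + 0.1069 * height + 0.2466 * mass
        raise ValueError(f"unknown sex {sex!r} for the Watson method")
    if method == "fraction":
        if fraction <= 0:
            raise ValueError("water fraction must be positive")
        return fraction * mass
    raise ValueError(f"unknown TBW method {method!r}")


def enrichment_from_doses(doses, tbw: float,
                          include_baseline: bool = False) -> float:
    """Asymptotic enrichment (atom %) from cumulative dose over TBW.

    ``100 * sum(volume * d2o_fraction) / (tbw * 1000)``, plus the 0.015%
    natural-abundance baseline when requested.  ``tbw`` is in litres,
    volumes in ml.
    """
    if tbw <= 0:
        raise ValueError("total body water must be positive")
    added = 100.0 * sum(d.d2o_volume for d in doses) / (tbw * 1000.0)
    return added + (NATURAL_ABUNDANCE_PCT if include_baseline else 0.0)


def cumulative_dose_series(doses, tbw: float,
                           include_baseline: bool = True) -> EnrichmentSeries:
    """Step series of asymptotic enrichment after each dose, over dose times."""
    if tbw <= 0:
        raise ValueError("total body water must be positive")
    doses = sorted(doses, key=lambda d: d.time)
    times = np.array([d.time for d in doses], dtype=float)
    steps = np.cumsum([100.0 * d.d2o_volume / (tbw * 1000.0) for d in doses])
    if include_baseline:
        steps = steps + NATURAL_ABUNDANCE_PCT
    return EnrichmentSeries(times, steps, provenance="from_dose")


def integrate_hdo_signal(frequency_hz, magnitude, window_hz: float) -> float:
    """Integrated HDO amplitude: sum of magnitude-spectrum samples within
    +/- ``window_hz`` of the (peak-centred) HDO resonance.

    Linear in the spectrum amplitude; with a window much wider than the
    linewidth the sum times the frequency step approximates the peak area.
    """
    f = np.asarray(frequency_hz, dtype=float)
    m = np.asarray(magnitude, dtype=float)
    if f.shape != m.shape or f.ndim != 1:
        raise ValueError("frequency and magnitude must be matching 1-D arrays")
    if window_hz <= 0:
        raise ValueError("integration window must be positive")
    if not np.any(m):
        return 0.0
    centre = f[int(np.argmax(np.abs(m)))]
    sel = np.abs(f - centre) <= window_hz
    if not np.any(sel):
        raise ValueError("integration window contains no samples")
    return float(np.sum(m[sel]))


def enrichment_from_signal(signal: float, baseline_signal: float,
                           natural_abundance: float = NATURAL_ABUNDANCE_PCT) -> float:
    """Enrichment (atom %) by scaling against the natural-abundance signal:
    ``natural_abundance * signal / baseline_signal``."""
    if baseline_signal <= 0:
        raise ValueError("baseline signal must be positive")
    if signal < 0:
        raise ValueError("signal must be non-negative")
    return natural_abundance * signal / baseline_signal


def normalize_timecourse(roi_series: pd.DataFrame, reference_roi: str,
                         reference_time: str = "last") -> pd.DataFrame:
    """Scale every ROI time-course by the reference ROI's final value.

    ``roi_series`` is a DataFrame indexed by time with one column per ROI.
    The reference ROI's value at the final time point maps to 1.0; all
    between-ROI ratios are preserved at every time point.
    """
    if reference_roi not in roi_series.columns:
        raise KeyError(f"reference ROI {reference_roi!r} not in series")
    if reference_time != "last":
        raise ValueError("only reference_time='last' is supported")
    ref = float(roi_series[reference_roi].iloc[-1])
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return roi_series / ref
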