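"""Published in-vivo reference values used for validation.

Per-visit ROI-mean relaxation times (ms) reported from a 7T study of four
healthy participants imaged while loaded with heavy water to ~1.5%
deuterium enrichment.  Six sessions contribute deuterium values (two
participants were scanned twice); four sessions contribute proton T2*
values.  Rows are (participant, visit) in acquisition order.

These numbers are inputs to the validation suite: tissue comparisons and
the printed group means are recomputed from them at run time.
"""

from __future__ import annotations

# 2H relaxation times per session, ms
D2_T1_MS = {
    "CSF": (450.0, 520.0, 460.0, 390.0, 720.0, 510.0),
    "GM": (280.0, 300.0, 301.0, 295.0, 420.0, 320.0),
    "WM": (260.0, 280.0, 290.0, 267.0, 350.0, 277.0),
}

D2_T2STAR_MS = {
    "CSF": (110.0, 83.0, 76.0, 82.0, 84.0, 110.0),
    "GM": (32.0, 33.0, 31.0, 32.0, 31.0, 31.0),
    "WM": (30.0, 32.0, 30.0, 32.0, 28.0, 28.0),
}

# 1H T2* per session, ms (one session per participant)
H1_T2STAR_MS = {
    "CSF": (106.0, 103.0, 93.0, 87.0),
    "GM": (26.0, 25.0, 22.0, 23.0),
    "WM": (27.0, 23.0, 21.0, 22.0),
}

# Group means as printed in the study's summary table, ms
PRINTED_MEANS = {
    ("2H", "T1", "CSF"): 510.0,
    ("2H", "T1", "GM"): 320.0,
    ("2H", "T1", "WM"): 290.0,
    ("2H", "T2star", "CSF"): 90.0,
    ("2H", "T2star", "GM"): 32.0,
    ("2H", "T2star", "WM"): 30.0,
    ("1H", "T2star", "CSF"): 97.0,
    ("1H", "T2star", "GM"): 24.0,
    ("1H", "T2star", "WM"): 23.0,
}

# Dosing regime: ~50 ml doses of 70% D2O / 30% H2O, one every ~30 min,
# targeting 1.5% body-water enrichment.
DOSE_VOLUME_ML = 50.0
DOSE_D2O_FRACTION = 0.70
DOSE_INTERVAL_MIN = 30.0
NATURAL_ABUNDANCE_PCT = 0.015
TARGET_ENRICHMENT_PCT = 1.5
ABSORPTION_HALF_LIFE_MIN = 12.0
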