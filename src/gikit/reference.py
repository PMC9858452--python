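"""Reference dataset: commercial biscuits with labelled clinical GI values.

Published composition and validation figures for a panel of fourteen
commercial biscuits digested under three static in vitro protocols — an
eight-sample calibration group (samples 1–8, one manufacturer, GI 9–30
by ISO 26642:2010) and a six-sample validation group (samples 9–14).
Used by the analysis drivers and the acceptance checks to exercise the
GL, correlation and error-rate arithmetic on real printed numbers.

Notes
-----
* ``CALIBRATION_GROUP`` carries the composition table (GI, GL, proximate
  percentages) of the calibration panel.
* ``VALIDATION_ROWS`` carries the labelled GI, reported eGI ± SD and
  relative error rate per sample and single-enzyme digestion model.
  The GI column of that validation table lists samples 1–8 in a different
  order than the composition table; the rows are kept exactly as printed
  and only rows whose error-rate arithmetic is self-consistent are marked
  ``arithmetic_consistent`` for assertion purposes.
* ``CALIBRATION_PANCREATIN`` / ``CALIBRATION_AMYLASE`` are the published
  AUCR180→GI calibration lines for the two single-enzyme protocols.
"""

from __future__ import annotations

import pandas as pd

from .types import Basis, CalibrationModel, Protocol

__all__ = [
    "CALIBRATION_GROUP",
    "VALIDATION_ROWS",
    "CALIBRATION_PANCREATIN",
    "CALIBRATION_AMYLASE",
    "calibration_group_frame",
    "validation_frame",
]

# sample_id, clinical_gi, gl, moisture, protein, fat, total_carb, starch_db, free_sugar
CALIBRATION_GROUP = [
    ("1", 9, 1.27, 4.48, 9.81, 42.85, 14.15, 7.33, 21.57),
    ("2", 9, 2.00, 4.59, 10.91, 43.24, 22.24, 8.10, 21.27),
    ("3", 11, 2.44, 5.42, 15.29, 39.56, 22.14, 6.45, 15.81),
    ("4", 13, 2.37, 5.43, 16.09, 35.83, 18.21, 11.91, 17.08),
    ("5", 13, 2.35, 6.62, 14.00, 36.00, 18.10, 11.65, 16.17),
    ("6", 13, 2.34, 6.69, 16.00, 39.00, 18.00, 8.93, 16.24),
    ("7", 16, 2.98, 5.23, 16.78, 39.17, 18.65, 9.57, 16.80),
    ("8", 30, 4.76, 5.80, 13.59, 39.65, 15.86, 9.95, 15.84),
]

_CAL_COLUMNS = [
    "sample_id", "clinical_gi", "gl", "moisture_pct", "protein_pct",
    "fat_pct", "total_carb_pct", "total_starch_pct_db", "free_sugar_pct",
]


def calibration_group_frame() -> pd.DataFrame:
    """Calibration-group composition table as a DataFrame."""
    return pd.DataFrame(CALIBRATION_GROUP, columns=_CAL_COLUMNS)


# Published AUCR180 -> GI calibration lines (reducing-sugar basis).
CALIBRATION_PANCREATIN = CalibrationModel(
    protocol=Protocol.PANCREATIN, basis=Basis.REDUCING_SUGAR_NORMALIZED,
    intercept_a=1.834, slope_b=0.009, r_squared=0.952, n=8,
)
CALIBRATION_AMYLASE = CalibrationModel(
    protocol=Protocol.AMYLASE, basis=Basis.REDUCING_SUGAR_NORMALIZED,
    intercept_a=6.101, slope_b=0.009, r_squared=0.902, n=8,
)

# sample_id, clinical_gi, protocol, egi, egi_sd, error_rate_pct, arithmetic_consistent
# (error_rate self-consistency: |egi - gi|/gi*100 rounds to the printed rate)
VALIDATION_ROWS = [
    ("1", 13, Protocol.PANCREATIN, 9.49, 5.55, 27.02, False),
    ("2", 13, Protocol.PANCREATIN, 12.63, 5.39, 2.87, False),
    ("3", 9, Protocol.PANCREATIN, 8.78, 5.61, 2.47, False),
    ("4", 11, Protocol.PANCREATIN, 12.08, 5.41, 9.85, False),
    ("5", 16, Protocol.PANCREATIN, 15.67, 5.38, 2.05, False),
    ("6", 13, Protocol.PANCREATIN, 13.82, 5.37, 6.28, False),
    ("7", 30, Protocol.PANCREATIN, 29.44, 6.98, 1.85, False),
    ("8", 9, Protocol.PANCREATIN, 12.30, 5.40, 36.67, True),
    ("9", 52, Protocol.PANCREATIN, 39.96, 9.26, 23.15, True),
    ("10", 53, Protocol.PANCREATIN, 38.43, 8.90, 27.48, False),
    ("11", 44, Protocol.PANCREATIN, 39.66, 9.19, 9.87, False),
    ("12", 30, Protocol.PANCREATIN, 49.11, 11.55, 63.70, True),
    ("13", 28, Protocol.PANCREATIN, 20.81, 5.70, 25.68, True),
    ("14", 19, Protocol.PANCREATIN, 13.87, 5.37, 27.01, False),
    ("1", 13, Protocol.AMYLASE, 10.72, 6.30, 17.52, False),
    ("2", 13, Protocol.AMYLASE, 13.18, 6.19, 1.37, False),
    ("3", 9, Protocol.AMYLASE, 11.22, 6.27, 24.72, False),
    ("4", 11, Protocol.AMYLASE, 12.36, 6.21, 12.35, False),
    ("5", 16, Protocol.AMYLASE, 13.19, 6.19, 17.55, False),
    ("6", 13, Protocol.AMYLASE, 11.23, 6.27, 13.61, False),
    ("7", 30, Protocol.AMYLASE, 30.05, 8.20, 0.16, False),
    ("8", 9, Protocol.AMYLASE, 12.32, 6.22, 36.87, False),
    ("9", 52, Protocol.AMYLASE, 28.74, 7.92, 44.74, False),
    ("10", 53, Protocol.AMYLASE, 31.75, 8.60, 40.09, True),
    ("11", 44, Protocol.AMYLASE, 26.38, 7.44, 40.05, True),
    ("12", 30, Protocol.AMYLASE, 41.20, 11.09, 37.33, True),
    ("13", 28, Protocol.AMYLASE, 20.54, 6.54, 26.65, False),
    ("14", 19, Protocol.AMYLASE, 19.07, 6.39, 0.37, True),
]

_VAL_COLUMNS = [
    "sample_id", "clinical_gi", "protocol", "egi", "egi_sd",
    "error_rate_pct", "arithmetic_consistent",
]


def validation_frame() -> pd.DataFrame:
    """Validation table (labelled GI, reported eGI ± SD, error rate)."""
    df = pd.DataFrame(VALIDATION_ROWS, columns=_VAL_COLUMNS)
    df["protocol"] = df["protocol"].map(lambda p: p.value)
    return df
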