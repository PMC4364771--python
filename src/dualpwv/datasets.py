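"""Embedded bench-validation measurements for worked examples and tests.

These are the printed results of an in-vitro validation of the dual-gate
Doppler PWV method on a homogeneous rubber tube: ten paired measurements of
the long-baseline pressure-referenced estimate (A→B, baselines of roughly
290–390 mm) against the local dual-gate estimate over a ~40 mm segment at
the middle of the tube, plus the observer-reproducibility summary (mean,
SD, mean difference ± SD of differences, CV%) for bench and in-vivo carotid
measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "bench_validation_table",
    "reproducibility_summary",
    "PRESSURE_TO_GATE_DELAYS_MS",
    "WORKED_TRANSIT_AB_MS",
    "WORKED_LOCAL_TRANSIT_MS",
    "COHORT_SUMMARY",
]

# long-baseline (A→B) columns: distance (mm), transit (ms), printed PWV (m/s)
_AB = [
    (389.3, 74.3, 5.24),
    (380.1, 75.2, 5.05),
    (376.4, 73.9, 5.09),
    (366.0, 76.4, 4.79),
    (351.0, 73.0, 4.81),
    (349.6, 69.6, 5.02),
    (320.7, 64.9, 4.94),
    (313.1, 61.9, 5.06),
    (301.0, 58.7, 5.13),
    (287.4, 55.6, 5.17),
]

# local dual-gate (middle segment) columns: distance (mm), transit (ms), printed PWV (m/s)
_M = [
    (38.4, 7.1, 5.41),
    (38.4, 7.4, 5.19),
    (39.7, 8.0, 4.96),
    (41.2, 8.6, 4.79),
    (40.4, 8.6, 4.70),
    (39.6, 7.3, 5.42),
    (41.2, 8.1, 5.09),
    (38.4, 6.9, 5.57),
    (39.8, 7.7, 5.17),
    (40.7, 7.7, 5.29),
]


def bench_validation_table() -> pd.DataFrame:
    """The ten paired bench measurements.

    Columns: ``dd_ab_mm``, ``dt_ab_ms``, ``pwv_ab_printed`` for the
    long-baseline estimate and ``dd_m_mm``, ``dt_m_ms``, ``pwv_m_printed``
    for the local dual-gate estimate; one row per measurement.
    """
    ab = np.array(_AB)
    m = np.array(_M)
    return pd.DataFrame(
        {
            "measurement": np.arange(1, 11),
            "dd_ab_mm": ab[:, 0],
            "dt_ab_ms": ab[:, 1],
            "pwv_ab_printed": ab[:, 2],
            "dd_m_mm": m[:, 0],
            "dt_m_ms": m[:, 1],
            "pwv_m_printed": m[:, 2],
        }
    )


_REPRO = [
    # label, mean, sd, mean_diff, sd_diff, printed CV%
    ("pwv_ab_intra_observer", 5.03, 0.13, -0.005, 0.05, 0.99),
    ("pwv_ab_inter_observer", 5.05, 0.15, -0.037, 0.10, 1.98),
    ("pwv_m_intra_observer", 5.20, 0.25, -0.078, 0.18, 3.46),
    ("pwv_m_inter_observer", 5.24, 0.32, -0.156, 0.26, 4.96),
    ("healthy_intra_observer", 5.31, 0.72, 0.001, 0.11, 2.07),
    ("healthy_inter_observer", 5.31, 0.74, -0.015, 0.22, 4.14),
    ("hypertensive_intra_observer", 6.30, 1.01, 0.013, 0.14, 2.22),
    ("hypertensive_inter_observer", 6.34, 1.05, -0.081, 0.25, 3.94),
]


def reproducibility_summary() -> pd.DataFrame:
    """Observer-reproducibility summary rows (bench and in-vivo carotid)."""
    return pd.DataFrame(
        _REPRO, columns=["label", "mean", "sd", "mean_diff", "sd_diff", "cv_printed"]
    )


#: Worked example: delays from the shared pressure-curve onset to the flow
#: foot at the upstream (A) and downstream (B) bench sites, in ms.
PRESSURE_TO_GATE_DELAYS_MS = {"A": 125.0, "B": 184.0}

#: The transit time those delays imply for the A→B segment: 184 − 125 ms.
WORKED_TRANSIT_AB_MS = 59.0

#: Worked example transit time of the local dual-gate measurement, ms.
WORKED_LOCAL_TRANSIT_MS = 9.0

#: In-vivo carotid cohort summaries: (mean m/s, SD m/s, n).
COHORT_SUMMARY = {
    "hypertensive": (6.29, 1.04, 45),
    "healthy": (5.31, 0.72, 45),
}
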