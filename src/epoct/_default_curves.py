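"""Built-in respiratory-rate and heart-rate percentile grids.

The triage rules threshold vital signs against age- and
temperature-corrected percentile curves (respiratory rate 75th/97th
percentile, heart rate 90th percentile). The primary literature behind
those curves is not reproduced here; these default grids are declared
approximations with the right shape — rates fall with age and rise with
temperature (roughly +2 breaths/min and +10 beats/min per degree C of
fever) — and are fully replaceable through the standards config.

Grid layout: rows = age nodes (months), columns = axillary temperature
nodes (deg C); lookups interpolate bilinearly inside the grid and clamp at
its edges.
"""
from __future__ import annotations

import numpy as np

AGE_NODES_MONTHS = np.array([2.0, 12.0, 24.0, 59.0])
TEMP_NODES_C = np.array([37.5, 38.0, 38.5, 39.0, 39.5, 40.0, 40.5])

# breaths/min, 75th percentile for age and temperature
RR_P75 = np.array(
    [
        [50.0, 51.0, 52.0, 53.0, 54.0, 55.0, 56.0],
        [43.0, 44.0, 45.0, 46.0, 47.0, 48.0, 49.0],
        [38.0, 39.0, 40.0, 41.0, 42.0, 43.0, 44.0],
        [33.0, 34.0, 35.0, 36.0, 37.0, 38.0, 39.0],
    ]
)

# breaths/min, 97th percentile for age and temperature
RR_P97 = np.array(
    [
        [66.0, 68.0, 70.0, 72.0, 74.0, 76.0, 78.0],
        [58.0, 60.0, 62.0, 64.0, 66.0, 68.0, 70.0],
        [52.0, 54.0, 56.0, 58.0, 60.0, 62.0, 64.0],
        [46.0, 48.0, 50.0, 52.0, 54.0, 56.0, 58.0],
    ]
)

# beats/min, 90th percentile for age and temperature
HR_P90 = np.array(
    [
        [165.0, 170.0, 175.0, 180.0, 185.0, 190.0, 195.0],
        [155.0, 160.0, 165.0, 170.0, 175.0, 180.0, 185.0],
        [150.0, 155.0, 160.0, 165.0, 170.0, 175.0, 180.0],
        [140.0, 145.0, 150.0, 155.0, 160.0, 165.0, 170.0],
    ]
)
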