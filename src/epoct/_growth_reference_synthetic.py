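"""Synthetic weight-for-age L/M/S growth-reference table.

This module ships a *synthetic* month-by-month L/M/S table for ages 0-60
months, built by monotone (PCHIP) interpolation through published summary
medians of the WHO 2006 weight-for-age standard. It is NOT the official
WHO table: the medians track the published curves to within a few hundred
grams, and the L (Box-Cox power) and S (coefficient of variation) columns
are smooth approximations. It exists so the severe-malnutrition criterion
(weight-for-age z-score < -3) is computable out of the box; users who need
the official standard can load their own table through the standards
config (``wfa_table`` key).

The z-score follows the standard LMS transform

    z = ((weight / M)**L - 1) / (L * S)        (L != 0)
    z = ln(weight / M) / S                     (L == 0)
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

# Anchor months and median weights (kg); smooth, monotone by construction.
_ANCHOR_MONTHS = np.array([0.0, 2.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0])
_ANCHOR_M = {
    "male": np.array([3.3, 5.6, 7.9, 9.6, 12.2, 14.3, 16.3, 18.3]),
    "female": np.array([3.2, 5.1, 7.3, 8.9, 11.5, 13.9, 16.1, 18.2]),
}
# Box-Cox power: positive and slowly declining with age.
_ANCHOR_L = {
    "male": np.array([0.35, 0.30, 0.26, 0.22, 0.18, 0.15, 0.12, 0.10]),
    "female": np.array([0.38, 0.33, 0.28, 0.24, 0.19, 0.16, 0.13, 0.11]),
}
# Coefficient of variation: minimum around the first birthday.
_ANCHOR_S = {
    "male": np.array([0.142, 0.126, 0.118, 0.116, 0.119, 0.123, 0.127, 0.131]),
    "female": np.array([0.143, 0.129, 0.121, 0.119, 0.122, 0.126, 0.130, 0.134]),
}

MONTHS = np.arange(0, 61, dtype=float)


def _interp(anchors: np.ndarray) -> np.ndarray:
    return PchipInterpolator(_ANCHOR_MONTHS, anchors)(MONTHS)


def default_lms_table() -> dict[str, dict[str, np.ndarray]]:
    """Month-by-month synthetic L/M/S arrays per sex, ages 0-60 months."""
    return {
        sex: {
            "L": _interp(_ANCHOR_L[sex]),
            "M": _interp(_ANCHOR_M[sex]),
            "S": _interp(_ANCHOR_S[sex]),
        }
        for sex in ("male", "female")
    }
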